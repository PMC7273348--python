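"""Ortholog calling, the pseudogene rule and fusion detection."""

import random

import pytest

from gablocks.blocks import build_blocks, render_block
from gablocks.orthology import (
    Hit,
    OrthologCall,
    ReferenceFamily,
    apply_pseudo_rule,
    call_orthologs,
    classify_pseudo,
    detect_fusions,
    read_hits_table,
    reference_families,
    search_hits,
    write_hits_table,
)
from gablocks.simulate import SimulationConfig, simulate_cohort


def _hit(label, subject, evalue, identity=0.9, qstart=1, qend=100, qlen=100):
    return Hit(
        query_label=label,
        subject_feature_id=subject,
        identity=identity,
        aligned_length=qend - qstart + 1,
        query_start=qstart,
        query_end=qend,
        subject_start=1,
        subject_end=qend - qstart + 1,
        evalue=evalue,
    )


class TestCallOrthologs:
    def test_evalue_boundary_is_inclusive(self):
        calls = call_orthologs([_hit("g", "f1", 1e-10)])
        assert len(calls) == 1 and calls[0].labels == ("g",)

    def test_evalue_above_threshold_is_discarded(self):
        assert call_orthologs([_hit("g", "f1", 1e-9)]) == []

    def test_best_family_wins(self):
        calls = call_orthologs(
            [_hit("k", "f1", 1e-12), _hit("g", "f1", 1e-30)]
        )
        assert len(calls) == 1
        assert calls[0].labels == ("g",)

    def test_tie_breaks_by_identity_then_label(self):
        calls = call_orthologs(
            [
                _hit("k", "f1", 1e-30, identity=0.8),
                _hit("g", "f1", 1e-30, identity=0.9),
            ]
        )
        assert calls[0].labels == ("g",)
        calls = call_orthologs(
            [
                _hit("k", "f1", 1e-30, identity=0.9),
                _hit("g", "f1", 1e-30, identity=0.9),
            ]
        )
        assert calls[0].labels == ("g",)  # label order: g before k

    def test_input_order_never_matters(self):
        rng = random.Random(0)
        hits = [
            _hit(lbl, f"f{i%3}", ev, identity=idt)
            for i, (lbl, ev, idt) in enumerate(
                [("g", 1e-30, 0.9), ("k", 1e-12, 0.95), ("h", 1e-25, 0.85),
                 ("b", 1e-40, 0.7), ("c", 1e-40, 0.7)]
            )
        ]
        ref = call_orthologs(hits)
        for _ in range(10):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            assert call_orthologs(shuffled) == ref

    def test_relaxing_threshold_never_removes_calls(self):
        hits = [_hit("g", "f1", 1e-12), _hit("h", "f2", 1e-8), _hit("i", "f3", 1e-30)]
        strict = {c.subject_feature_id for c in call_orthologs(hits, evalue_max=1e-10)}
        relaxed = {c.subject_feature_id for c in call_orthologs(hits, evalue_max=1e-6)}
        assert strict <= relaxed


class TestPseudoRule:
    family = ReferenceFamily("a", "cyp115", 1000)

    def _call(self, identity):
        return OrthologCall("f1", ("a",), "full", (_hit("a", "f1", 1e-20, identity),))

    def test_short_and_similar_is_pseudo(self):
        assert classify_pseudo(self._call(0.60), self.family, 550) == "pseudo"

    def test_long_is_full(self):
        assert classify_pseudo(self._call(0.60), self.family, 900) == "full"

    def test_sixty_percent_boundary_is_strictly_full(self):
        assert classify_pseudo(self._call(0.60), self.family, 600) == "full"
        assert classify_pseudo(self._call(0.60), self.family, 599) == "pseudo"

    def test_identity_boundary_is_strictly_above(self):
        assert classify_pseudo(self._call(0.50), self.family, 500) == "full"
        assert classify_pseudo(self._call(0.51), self.family, 500) == "pseudo"

    def test_zero_length_reference_is_invalid(self):
        with pytest.raises(ValueError):
            ReferenceFamily("a", "cyp115", 0)

    def test_rule_applies_to_cyp115_only_by_default(self):
        calls = [
            OrthologCall("f1", ("a",), "full", (_hit("a", "f1", 1e-20, 0.9),)),
            OrthologCall("f2", ("b",), "full", (_hit("b", "f2", 1e-20, 0.9),)),
        ]
        fams = [ReferenceFamily("a", "cyp115", 1000), ReferenceFamily("b", "cyp112", 1000)]
        out = apply_pseudo_rule(calls, fams, {"f1": 400, "f2": 400})
        assert [c.status for c in out] == ["pseudo", "full"]


class TestFusions:
    fams = [ReferenceFamily(l, n, 300) for l, n in [("c", "cyp114"), ("d", "fd"), ("e", "sdr")]]

    def _calls(self, with_d=False):
        calls = [
            OrthologCall("fc", ("c",), "full"),
            OrthologCall("fe", ("e",), "full"),
        ]
        if with_d:
            calls.append(OrthologCall("fd", ("d",), "full"))
        return calls

    def test_fd_sdr_fusion_detected(self):
        d_hit = _hit("d", "fe", 1e-20, qstart=1, qend=240, qlen=300)
        out = detect_fusions(self._calls(), [d_hit], d_query_length=300)
        fused = {c.subject_feature_id: c for c in out}["fe"]
        assert fused.status == "fusion" and fused.labels == ("d", "e")

    def test_cyp114_fd_fusion_detected(self):
        d_hit = _hit("d", "fc", 1e-20, qstart=1, qend=240)
        out = detect_fusions(self._calls(), [d_hit], d_query_length=300)
        fused = {c.subject_feature_id: c for c in out}["fc"]
        assert fused.status == "fusion" and fused.labels == ("c", "d")

    def test_standalone_fd_suppresses_fusion(self):
        d_hit = _hit("d", "fe", 1e-20, qstart=1, qend=240)
        out = detect_fusions(self._calls(with_d=True), [d_hit], d_query_length=300)
        assert all(c.status != "fusion" for c in out)

    def test_low_coverage_is_ignored(self):
        d_hit = _hit("d", "fc", 1e-20, qstart=1, qend=90)  # coverage 0.3
        out = detect_fusions(self._calls(), [d_hit], d_query_length=300)
        assert all(c.status != "fusion" for c in out)


def test_hits_table_roundtrip(tmp_path):
    hits = [
        _hit("g", "f1", 1e-30, identity=0.913),
        _hit("a", "f2", 1e-12, identity=0.55),
    ]
    path = tmp_path / "hits.tsv"
    write_hits_table(hits, str(path))
    back = read_hits_table(str(path))
    assert [(h.query_label, h.subject_feature_id) for h in back] == [
        ("g", "f1"), ("a", "f2")
    ]
    assert back[0].identity == pytest.approx(0.913, abs=1e-4)


def test_classification_on_synthetic_truth_is_perfect():
    """On simulated genomes, full/pseudo classification reaches precision and
    recall 1.0 when divergence keeps identity high and E-values tiny."""
    cfg = SimulationConfig(n_leaves=6, seed=21, rate_pseudogenize=0.15,
                           rate_deletion=0.02)
    cohort = simulate_cohort(cfg)
    fams = reference_families({l: cohort.templates[l] for l in "abcdefghijk"})
    for leaf, genome in cohort.genomes.items():
        hits = search_hits(genome, fams)
        calls = call_orthologs(hits, fams)
        lengths = {f.feature_id: f.length for f in genome.features}
        calls = apply_pseudo_rule(
            calls, fams, lengths, target_labels=tuple("abcdefghijk")
        )
        truth = {
            f.feature_id: f.family_hint
            for f in genome.features
            if f.family_hint in set("abcdefghijk")
        }
        called = {c.subject_feature_id: c for c in calls}
        for fid, label in truth.items():
            assert fid in called, f"{leaf}: missed {fid}"
            assert called[fid].labels == (label,), f"{leaf}: wrong family for {fid}"
            truncated = genome.feature_by_id(fid).length < 0.6 * len(
                cohort.templates[label]
            )
            expected_status = "pseudo" if truncated else "full"
            assert called[fid].status == expected_status, f"{leaf}: {fid}"
        # no spurious operon calls on the marker
        marker_ids = {f.feature_id for f in genome.features if f.family_hint == "marker"}
        assert marker_ids.isdisjoint(called)
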