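import random

import dendropy
import pytest


def rooted_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def random_block_string(rng: random.Random, families: str = "abcd",
                        max_copies: int = 2, split_prob: float = 0.4) -> str:
    """A random block string (possibly empty) over the given families."""
    picked = rng.sample(families, rng.randint(0, len(families)))
    genes = []
    for fam in picked:
        genes += [fam] * rng.randint(1, max_copies)
    rng.shuffle(genes)
    if not genes:
        return ""
    if len(genes) > 1 and rng.random() < split_prob:
        cut = rng.randint(1, len(genes) - 1)
        return "".join(genes[:cut]) + "|" + "".join(genes[cut:])
    return "".join(genes)


@pytest.fixture
def quartet():
    return rooted_tree("((L1:1,L2:1):1,(L3:1,L4:1):1);")
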