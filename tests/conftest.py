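import pytest

from riverine.treeio import Tree, parse_newick


@pytest.fixture
def three_tip_tree():
    """((A,B),C) with unit lengths except C."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def cherry_species_tree():
    """Dated 6-species tree with three cherries (ages 1, 2, 2.5; root 4)."""
    return Tree.from_nested(
        (
            None,
            0.0,
            [
                (None, 3.0, [("sp_a", 1.0, []), ("sp_b", 1.0, [])]),
                (
                    None,
                    0.5,
                    [
                        (None, 1.5, [("sp_c", 2.0, []), ("sp_d", 2.0, [])]),
                        (None, 1.0, [("sp_e", 2.5, []), ("sp_f", 2.5, [])]),
                    ],
                ),
            ],
        )
    )
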