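import numpy as np
import pytest

from rpipred import FixtureSpec, make_classified_pairs, make_four_chain_complex


@pytest.fixture(scope="session")
def four_chain_complex():
    """Synthetic four-protein/two-RNA complex (A==C, B==D, Q==R)."""
    return make_four_chain_complex()


@pytest.fixture(scope="session")
def separable_table():
    """Classified pair table with disjoint class compositions."""
    table, truth = make_classified_pairs(
        FixtureSpec(n_pairs=60, protein_len=80, rna_len=40, separation=6.0, seed=11)
    )
    return table, truth


def random_nested_dot_bracket(rng: np.random.Generator, n: int) -> str:
    """Random balanced dot-bracket string of length n (nested by construction)."""
    out = []
    open_count = 0
    for i in range(n):
        remaining = n - i
        choices = ["."]
        if remaining > open_count + 1:
            choices.append("(")
        if open_count > 0:
            choices.append(")")
        ch = rng.choice(choices)
        if ch == "(":
            open_count += 1
        elif ch == ")":
            open_count -= 1
        out.append(ch)
    # close whatever is left
    while open_count > 0:
        out.append(")")
        open_count -= 1
    return "".join(out)
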