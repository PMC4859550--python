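import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from yeastevol.trees import guide_tree

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

UNIFORM_PI = np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def uniform_pi():
    return UNIFORM_PI.copy()


@pytest.fixture
def seven_taxon_tree():
    """The fixed guide tree with the Dekkera clade as foreground (#1)."""
    return guide_tree(0.2)


def make_synthetic_pdb(atoms):
    """Build PDB ATOM-record text from (chain, resseq, resname, atomname,
    x, y, z) tuples — a synthetic structure for geometry tests."""
    lines = []
    for serial, (chain, resseq, resname, atomname, x, y, z) in enumerate(atoms, 1):
        pad = atomname if len(atomname) == 4 else f" {atomname:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {pad} {resname:>3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{atomname[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
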