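import numpy as np
import pytest

from phocomp.syndata import (FamilySpec, MotifPlant, SpeciesSpec, SSRPlant,
                             default_families, default_species, generate_panel)


def small_species():
    """Reference monocot, one diverged monocot, one dicot."""
    return (SpeciesSpec("Mon1", "monocot", 0.0),
            SpeciesSpec("Mon2", "monocot", 0.06),
            SpeciesSpec("Dic1", "dicot", 0.12))


def small_families(seed):
    """Compact variants of the two default families (shorter introns/core)
    so multi-panel sweeps stay fast; structure is otherwise identical."""
    pho1, pho2 = default_families(seed)
    small = dict(core_len=300, intron_len_range=(60, 200))
    from dataclasses import replace
    return (replace(pho1, **small), replace(pho2, **small))


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(small_species(), small_families(11))


@pytest.fixture(scope="session")
def full_panel():
    """The default study conditions: 8 monocots + 4 dicots, both families."""
    return generate_panel(default_species(), default_families(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
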