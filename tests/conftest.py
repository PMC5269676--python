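import pytest

from paragraft import synthfix
from paragraft.grafting import residue_triplet_vertices


@pytest.fixture(scope="session")
def hotspot_fixture():
    """(HotspotSet, donor complex, 9-vertex triplet) of the toy ETGE-like donor."""
    hotspots, complex_structure = synthfix.make_hotspot_complex(0)
    vertices = residue_triplet_vertices(hotspots.residues)
    return hotspots, complex_structure, vertices


@pytest.fixture(scope="session")
def toy_design():
    """Heavy-chain design with a length-13 hairpin CDRH3 (residues 85-110)."""
    return synthfix.make_toy_design(seed=0, loop_length=13)


@pytest.fixture(scope="session")
def toy_fv():
    """Two-domain Cα-trace Fv in the canonical packing."""
    return synthfix.make_toy_fv(seed=0)


@pytest.fixture(scope="session")
def contact_slabs():
    """Complementary flat slabs at vdW contact, split into the two chains."""
    pair = synthfix.make_interface_pair(gap=0.0, bumpiness=0.0, seed=0)
    return pair.subset(["A"]), pair.subset(["B"])
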