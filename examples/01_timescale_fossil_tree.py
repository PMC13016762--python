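"""Date a fossil cladogram with the equal and mbl methods.

A fossil tree arrives as topology plus tip ages (FAD/LAD in Ma); both
scalers must remove the zero-length branches created when a node's age
equals its oldest descendant's.
"""

import asekit as ak
from asekit.trees import TaxonAges, read_tree

topology = read_tree("(((Anchiornis,Archaeopteryx),Velociraptor),Coelophysis);")
ages = TaxonAges(
    fad={"Anchiornis": 160, "Archaeopteryx": 150, "Velociraptor": 75, "Coelophysis": 215},
    lad={"Anchiornis": 155, "Archaeopteryx": 148, "Velociraptor": 71, "Coelophysis": 208},
)

equal = ak.timescale_equal(topology, ages, root_length=1.0)
mbl = ak.timescale_mbl(topology, ages, min_length=1.0, root_length=1.0)

print("equal-method node ages (Ma):", {k: round(v, 2) for k, v in equal.node_ages().items()})
print("mbl node ages (Ma):        ", {k: round(v, 2) for k, v in mbl.node_ages().items()})
print("shortest equal branch:", round(min(equal.branch_lengths().values()), 3), "myr")
print("shortest mbl branch:  ", round(min(mbl.branch_lengths().values()), 3), "myr")
# Ages increase into the past; every branch is strictly positive, with the
# mbl tree guaranteeing at least the configured 1-myr minimum.
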