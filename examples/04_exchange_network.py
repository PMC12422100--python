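"""Who feeds whom: the quad-culture cross-feeding network.

Takes the quad-culture's true reaction extents and reads off the exchange
network: each metabolite's producers and consumers, with intra-species
recycling netted out and multi-donor supplies split by production share.
The emergent routes (Dv -> Mc acetate, Mc -> Mh CO2, Dv -> Mh H2) only
exist with three or more species present.
"""

from syntroflux import Assembly, infer_exchanges, load_catalog
from syntroflux.synthetic import PRESET_EXTENTS

catalog = load_catalog()
extents = PRESET_EXTENTS["Rc&Mc&Mh&Dv"]
edges = infer_exchanges(extents, Assembly.from_label("Rc&Mc&Mh&Dv"),
                        catalog, convention="metabolite_total")

print(f"{'donor':6s} {'receiver':9s} {'metabolites':16s} {'mmol':>8s}")
for e in sorted(edges, key=lambda e: -e.amount):
    print(f"{e.donor:6s} {e.receiver:9s} {'+'.join(sorted(e.metabolites)):16s} "
          f"{e.amount:8.3f}")
print("\nAmounts are total mmol transferred along each route over the run "
      "(metabolite_total convention); switch to 'consumer_extent' to label "
      "edges with the receiving reaction's extent instead.")
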