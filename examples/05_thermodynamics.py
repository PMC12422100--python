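"""Why hydrogen removal matters: ΔG′ of methanogenesis vs H2 pressure.

ΔG′ = ΔG°′ + RT ln Q at 298.15 K.  Hydrogenotrophic methanogenesis consumes
four H2 per CH4, so every tenfold drop in H2 partial pressure costs it
4 x 5.708 = 22.8 kJ/mol of driving force — the thermodynamic core of
interspecies hydrogen transfer.
"""

from syntroflux import ChemicalState, delta_g_prime, load_catalog

catalog = load_catalog()
rxn = catalog.reaction("hydrogenotrophic_methanogenesis")

print(f"{rxn.id}:  4 H2 + CO2 -> CH4   (dG0' = {rxn.dg0_prime} kJ/mol)\n")
print(f"{'pH2 (atm)':>10s} {'Q':>12s} {'dG_prime (kJ/mol)':>18s}")
for ph2 in [1.0, 0.1, 0.01, 1e-3, 1e-4]:
    state = ChemicalState(aqueous={}, gas={"H2": ph2, "CO2": 0.2, "CH4": 0.5})
    res = delta_g_prime(rxn, state, catalog)
    print(f"{ph2:10.0e} {res.quotient:12.3e} {res.dg_prime:18.2f}")
print("\nEach decade of H2 costs 22.8 kJ/mol: methanogens keep the reaction "
      "running only while fermenters keep supplying H2 — and fermenters "
      "need methanogens to keep pH2 low enough for their own reactions.")
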