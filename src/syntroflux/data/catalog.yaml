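# Default reaction catalogue for the four-species cellulolytic community.
#
# Cellulose is fed as glucose-equivalent (anhydroglucose); hydrolysis itself
# is not a fitted reaction.  Water and protons are implicit: the pH-7
# transformed-energy convention absorbs them, and they carry no carbon or
# combustion electrons.  All stoichiometries, ATP yields and standard
# transformed Gibbs energies (dg0_prime, kJ per unit extent at pH 7, 25 C)
# may be overridden by pointing the loader at an edited copy of this file.
version: "1.0"

species:
  Rc: Ruminiclostridium cellulolyticum (cellulolytic fermenter)
  Mc: Methanosaeta concilii (acetoclastic methanogen)
  Mh: Methanospirillum hungatei (hydrogenotrophic methanogen)
  Dv: Desulfovibrio vulgaris (sulfate reducer; lactate oxidizer without sulfate)

metabolites:
  glucose:  {formula: {C: 6, H: 12, O: 6}, phase: aqueous, carbon: 6, gamma: 24}
  lactate:  {formula: {C: 3, H: 6,  O: 3}, phase: aqueous, carbon: 3, gamma: 12}
  acetate:  {formula: {C: 2, H: 4,  O: 2}, phase: aqueous, carbon: 2, gamma: 8}
  ethanol:  {formula: {C: 2, H: 6,  O: 1}, phase: aqueous, carbon: 2, gamma: 12}
  formate:  {formula: {C: 1, H: 2,  O: 2}, phase: aqueous, carbon: 1, gamma: 2}
  H2:       {formula: {C: 0, H: 2,  O: 0}, phase: gas,     carbon: 0, gamma: 2}
  CO2:      {formula: {C: 1, H: 0,  O: 2}, phase: gas,     carbon: 1, gamma: 0}
  CH4:      {formula: {C: 1, H: 4,  O: 0}, phase: gas,     carbon: 1, gamma: 8}

# Order below is the canonical reaction order used everywhere downstream.
reactions:
  lactate_fermentation:
    species: Rc
    stoich: {glucose: -1, lactate: 2}
    atp_yield: 2
    dg0_prime: -196.0
  hydrogenic_acetogenesis:
    species: Rc
    stoich: {glucose: -1, acetate: 2, CO2: 2, H2: 4}
    atp_yield: 4
    dg0_prime: -206.3
  mixed_acid_fermentation:
    species: Rc
    stoich: {glucose: -1, ethanol: 1, acetate: 1, CO2: 2, H2: 2}
    atp_yield: 3
    dg0_prime: -220.0
  hydrogenic_lactate_oxidation:
    species: Dv
    stoich: {lactate: -1, acetate: 1, CO2: 1, H2: 2}
    atp_yield: 1
    dg0_prime: -4.2
  hydrogenotrophic_methanogenesis:
    species: Mh
    stoich: {H2: -4, CO2: -1, CH4: 1}
    atp_yield: 0.5
    dg0_prime: -131.0
  acetoclastic_methanogenesis:
    species: Mc
    stoich: {acetate: -1, CH4: 1, CO2: 1}
    atp_yield: 0.25
    dg0_prime: -36.0

# Biomass pseudo-metabolite: grams produced per mol ATP (Y_ATP).
biomass:
  y_atp: 10.5
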