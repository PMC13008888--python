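# Drug-likeness rule constants, pinned from the published criteria.
# All bounds are inclusive. Lipinski passes with at most `max_violations`
# violated sub-criteria; every other rule requires all sub-criteria.
lipinski:
  max_violations: 1
  criteria:
    mw_max: 500.0          # g/mol, uses consensus log P for the logp bound
    logp_max: 5.0
    hbd_max: 5
    hba_max: 10
ghose:
  criteria:
    mw_min: 160.0
    mw_max: 480.0
    wlogp_min: -0.4
    wlogp_max: 5.6
    mr_min: 40.0
    mr_max: 130.0
    atoms_min: 20
    atoms_max: 70
veber:
  criteria:
    rotb_max: 10
    tpsa_max: 140.0
egan:
  criteria:
    wlogp_max: 5.88
    tpsa_max: 131.6
muegge:
  criteria:
    mw_min: 200.0
    mw_max: 600.0
    xlogp_min: -2.0
    xlogp_max: 5.0
    tpsa_max: 150.0
    rings_max: 7
    carbon_min_exclusive: 4
    heteroatom_min_exclusive: 1
    rotb_max: 15
    hba_max: 10
    hbd_max: 5
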