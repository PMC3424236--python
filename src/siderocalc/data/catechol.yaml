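# Fe(III) / catechol (1,2-dihydroxybenzene) equilibrium scheme.
# Conditional literature reconstructions (I ~ 0.1 M, ~25 C); L = catecholate dianion.
name: catechol
kw: -13.997
ionic_strength_note: "conditional constants, I ~ 0.1 M; no activity corrections"
temperature_note: "~25 C"
components:
  - {name: Fe, charge: 3, role: metal}
  - {name: L, charge: -2, role: ligand}
  - {name: H, charge: 1, role: proton}
  - {name: P, charge: 0, role: protein}
species:
  - {label: LH, stoich: {L: 1, H: 1}, log_beta: 13.0,
     provenance: "reconstructed; catechol pKa2 ~ 13.0 (Avdeef et al. 1978)"}
  - {label: LH2, stoich: {L: 1, H: 2}, log_beta: 22.22,
     provenance: "reconstructed; + pKa1 9.22 (Avdeef et al. 1978)"}
  - {label: FeL, stoich: {Fe: 1, L: 1}, log_beta: 20.01,
     provenance: "reconstructed; Avdeef et al. 1978"}
  - {label: FeL2, stoich: {Fe: 1, L: 2}, log_beta: 34.70,
     provenance: "reconstructed; Avdeef et al. 1978"}
  - {label: FeL3, stoich: {Fe: 1, L: 3}, log_beta: 43.76,
     provenance: "reconstructed; Avdeef et al. 1978"}
  - {label: FeOH, stoich: {Fe: 1, H: -1}, log_beta: -2.19,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH2, stoich: {Fe: 1, H: -2}, log_beta: -5.67,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH4, stoich: {Fe: 1, H: -4}, log_beta: -21.6,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
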