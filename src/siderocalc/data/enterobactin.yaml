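# Fe(III) / enterobactin (Ent) equilibrium scheme.
# Ent is the hexadentate tris-catecholate siderophore; L = fully deprotonated
# hexaanion.  Conditional literature reconstructions (I ~ 0.1 M, ~25 C).
name: enterobactin
kw: -13.997
ionic_strength_note: "conditional constants, I ~ 0.1 M; no activity corrections"
temperature_note: "~25 C"
components:
  - {name: Fe, charge: 3, role: metal}
  - {name: L, charge: -6, role: ligand}
  - {name: H, charge: 1, role: proton}
  - {name: P, charge: 0, role: protein}
species:
  # six catechol OH protonations, cumulative (three "high" then three "low" pKa)
  - {label: LH, stoich: {L: 1, H: 1}, log_beta: 11.7,
     provenance: "reconstructed; catecholate 3-OH pKa, estimated"}
  - {label: LH2, stoich: {L: 1, H: 2}, log_beta: 23.4,
     provenance: "reconstructed"}
  - {label: LH3, stoich: {L: 1, H: 3}, log_beta: 35.1,
     provenance: "reconstructed"}
  - {label: LH4, stoich: {L: 1, H: 4}, log_beta: 43.9,
     provenance: "reconstructed; 2-OH pKa 8.8"}
  - {label: LH5, stoich: {L: 1, H: 5}, log_beta: 52.1,
     provenance: "reconstructed; 2-OH pKa 8.2"}
  - {label: LH6, stoich: {L: 1, H: 6}, log_beta: 59.6,
     provenance: "reconstructed; 2-OH pKa 7.5"}
  - {label: FeL, stoich: {Fe: 1, L: 1}, log_beta: 49.0,
     provenance: "reconstructed; hexadentate FeEnt log beta ~ 49 (Loomis & Raymond 1991)"}
  - {label: FeOH, stoich: {Fe: 1, H: -1}, log_beta: -2.19,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH2, stoich: {Fe: 1, H: -2}, log_beta: -5.67,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH4, stoich: {Fe: 1, H: -4}, log_beta: -21.6,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
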