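# Fe(III) / salicylic acid (SA, 2-hydroxybenzoic acid) equilibrium scheme.
# Conditional literature reconstructions (I ~ 0.1 M, ~25 C);
# L = salicylate dianion (carboxylate + 2-O-).
name: salicylate
kw: -13.997
ionic_strength_note: "conditional constants, I ~ 0.1 M; no activity corrections"
temperature_note: "~25 C"
components:
  - {name: Fe, charge: 3, role: metal}
  - {name: L, charge: -2, role: ligand}
  - {name: H, charge: 1, role: proton}
  - {name: P, charge: 0, role: protein}
species:
  - {label: LH, stoich: {L: 1, H: 1}, log_beta: 13.4,
     provenance: "reconstructed; phenolic 2-OH pKa of salicylate"}
  - {label: LH2, stoich: {L: 1, H: 2}, log_beta: 16.37,
     provenance: "reconstructed; + carboxyl pKa 2.97"}
  - {label: FeL, stoich: {Fe: 1, L: 1}, log_beta: 16.35,
     provenance: "reconstructed; Fe(III)-salicylate 1:1 literature range"}
  - {label: FeL2, stoich: {Fe: 1, L: 2}, log_beta: 27.0,
     provenance: "reconstructed; within literature range, consistent with study speciation"}
  - {label: FeL3, stoich: {Fe: 1, L: 3}, log_beta: 35.3,
     provenance: "reconstructed; tris salicylate complex"}
  - {label: FeOH, stoich: {Fe: 1, H: -1}, log_beta: -2.19,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH2, stoich: {Fe: 1, H: -2}, log_beta: -5.67,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH4, stoich: {Fe: 1, H: -4}, log_beta: -21.6,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
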