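# Fe(III) / 2,3-dihydroxybenzoic acid (2,3-DHBA) equilibrium scheme.
# All constants are conditional (I ~ 0.1 M, ~25 C) literature reconstructions,
# not asserted ground truth; see docs/methods.md for how they were chosen.
# L = fully deprotonated 2,3-DHBA trianion (carboxylate + 2-O- + 3-O-).
name: dhba23
kw: -13.997
ionic_strength_note: "conditional constants, I ~ 0.1 M; no activity corrections"
temperature_note: "~25 C"
components:
  - {name: Fe, charge: 3, role: metal}
  - {name: L, charge: -3, role: ligand}
  - {name: H, charge: 1, role: proton}
  - {name: P, charge: 0, role: protein}
species:
  # ligand protonation (cumulative)
  - {label: LH, stoich: {L: 1, H: 1}, log_beta: 11.7,
     provenance: "reconstructed; 3-OH pKa of 2,3-DHBA, catecholate literature range"}
  - {label: LH2, stoich: {L: 1, H: 2}, log_beta: 21.76,
     provenance: "reconstructed; + 2-OH pKa 10.06"}
  - {label: LH3, stoich: {L: 1, H: 3}, log_beta: 24.48,
     provenance: "reconstructed; + carboxyl pKa 2.72"}
  # Fe(III) complexes (catecholate-mode chelation)
  - {label: FeL, stoich: {Fe: 1, L: 1}, log_beta: 20.4,
     provenance: "reconstructed; catecholate-mode 1:1, consistent with study speciation"}
  - {label: FeL2, stoich: {Fe: 1, L: 2}, log_beta: 32.0,
     provenance: "reconstructed; consistent with study speciation"}
  - {label: FeL3, stoich: {Fe: 1, L: 3}, log_beta: 40.0,
     provenance: "reconstructed; consistent with study speciation"}
  # ferric hydrolysis (Baes & Mesmer 1976, mononuclear aqueous set)
  - {label: FeOH, stoich: {Fe: 1, H: -1}, log_beta: -2.19,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH2, stoich: {Fe: 1, H: -2}, log_beta: -5.67,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH4, stoich: {Fe: 1, H: -4}, log_beta: -21.6,
     provenance: "Baes & Mesmer 1976 (reconstructed); Fe(OH)3(aq) omitted, see docs"}
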