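# Fe(III) / gentisic acid (GA, 2,5-dihydroxybenzoic acid) equilibrium scheme.
# GA is an obligate salicylate-mode chelator (2-O- + carboxylate); the remote
# 5-OH stays protonated in the physiological complex FeLH.
# Conditional literature reconstructions (protonation and Fe formation constants
# per the 2,5-DHBA source cited by the study); L = fully deprotonated trianion.
name: gentisate
kw: -13.997
ionic_strength_note: "conditional constants, I ~ 0.1 M; no activity corrections"
temperature_note: "~25 C"
components:
  - {name: Fe, charge: 3, role: metal}
  - {name: L, charge: -3, role: ligand}
  - {name: H, charge: 1, role: proton}
  - {name: P, charge: 0, role: protein}
species:
  - {label: LH, stoich: {L: 1, H: 1}, log_beta: 13.0,
     provenance: "reconstructed; 2-OH pKa (H-bonded to carboxylate)"}
  - {label: LH2, stoich: {L: 1, H: 2}, log_beta: 23.2,
     provenance: "reconstructed; + 5-OH pKa 10.2"}
  - {label: LH3, stoich: {L: 1, H: 3}, log_beta: 26.17,
     provenance: "reconstructed; + carboxyl pKa 2.97"}
  # salicylate-mode Fe complexes; FeLH carries the protonated 5-OH
  - {label: FeL, stoich: {Fe: 1, L: 1}, log_beta: 16.0,
     provenance: "reconstructed; salicylate-mode 1:1 with 5-O- deprotonated"}
  - {label: FeLH, stoich: {Fe: 1, L: 1, H: 1}, log_beta: 26.2,
     provenance: "reconstructed; FeL + 5-OH protonation (~10.2)"}
  - {label: FeL2H2, stoich: {Fe: 1, L: 2, H: 2}, log_beta: 46.4,
     provenance: "reconstructed; bis salicylate-mode complex, 5-OH protonated"}
  - {label: FeOH, stoich: {Fe: 1, H: -1}, log_beta: -2.19,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH2, stoich: {Fe: 1, H: -2}, log_beta: -5.67,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
  - {label: FeOH4, stoich: {Fe: 1, H: -4}, log_beta: -21.6,
     provenance: "Baes & Mesmer 1976 (reconstructed)"}
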