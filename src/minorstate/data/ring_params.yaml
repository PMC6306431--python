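# Ring-current parameters: Haigh-Mallion geometric model.
#
# scale_b: overall calibration constant (dimensionless shielding per A^-3,
# proton-calibrated; reported shifts are scale_b * 1e6 * intensity * G ppm).
# intensity: ring-current intensity factor relative to benzene. Purine bases
# contribute two rings (5- and 6-membered) with separate factors; pyrimidines
# one. These are transcribed literature calibration values and are
# configuration, not hard-coded truths: supply an alternative file to the
# loader to change them.
scale_b: 5.455e-6
rings:
  - {resname: PHE, name: six, intensity: 1.05, atoms: [CG, CD1, CE1, CZ, CE2, CD2]}
  - {resname: TYR, name: six, intensity: 0.92, atoms: [CG, CD1, CE1, CZ, CE2, CD2]}
  - {resname: HIS, name: five, intensity: 0.675, atoms: [CG, ND1, CE1, NE2, CD2]}
  - {resname: TRP, name: five, intensity: 1.04, atoms: [CG, CD1, NE1, CE2, CD2]}
  - {resname: TRP, name: six, intensity: 1.02, atoms: [CD2, CE3, CZ3, CH2, CZ2, CE2]}
  # Nucleobases (DNA and RNA residue names)
  - {resname: DA, name: six, intensity: 0.90, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: DA, name: five, intensity: 1.16, atoms: [C4, C5, N7, C8, N9]}
  - {resname: A,  name: six, intensity: 0.90, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: A,  name: five, intensity: 1.16, atoms: [C4, C5, N7, C8, N9]}
  - {resname: DG, name: six, intensity: 0.30, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: DG, name: five, intensity: 0.64, atoms: [C4, C5, N7, C8, N9]}
  - {resname: G,  name: six, intensity: 0.30, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: G,  name: five, intensity: 0.64, atoms: [C4, C5, N7, C8, N9]}
  - {resname: DC, name: six, intensity: 0.28, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: C,  name: six, intensity: 0.28, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: DT, name: six, intensity: 0.11, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: T,  name: six, intensity: 0.11, atoms: [N1, C2, N3, C4, C5, C6]}
  - {resname: U,  name: six, intensity: 0.11, atoms: [N1, C2, N3, C4, C5, C6]}
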