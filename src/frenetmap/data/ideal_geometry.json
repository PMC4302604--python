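{
  "comment": "Ideal covalent geometry used by the synthetic backbone generator and as reconstruction fallback radii. Lengths in angstrom, angles in degrees; values follow the high-resolution small-molecule (Engh-Huber-type) tradition.",
  "bond_lengths": {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-O": 1.231,
    "C-N": 1.329,
    "CA-CB": 1.530,
    "CB-CG": 1.520,
    "CG-CD": 1.520
  },
  "angles": {
    "theta_NC": 110.5,
    "theta_Nbeta": 111.2,
    "theta_betaC": 110.1,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "CA-CB-CG": 113.8,
    "CB-CG-CD": 111.3
  },
  "omega_trans_deg": 180.0,
  "omega_cis_deg": 0.0,
  "virtual_bond_A": 3.80
}
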