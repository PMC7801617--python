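# Talin-1 domain architecture frozen from structure-fragment and construct
# boundaries; gaps between cited anchors are closed by extending the earlier
# domain to the next domain's start-1. R7 is discontinuous (wraps the
# inserted R8); R9 is trimmed to start at 1660 to avoid overlap with the R7
# second segment (1585-1659).
protein: TLN1 (synthetic reference)
length: 2541
rsa_threshold: 0.20
domains:
  - {name: F0, segments: [[1, 85]]}
  - {name: F1, segments: [[86, 207]]}
  - {name: F2, segments: [[208, 308]]}
  - {name: F3, segments: [[309, 405]]}
  - {name: linker, segments: [[406, 481]]}
  - {name: R1, segments: [[482, 656]]}
  - {name: R2, segments: [[657, 795]]}
  - {name: R3, segments: [[796, 909]]}
  - {name: R4, segments: [[910, 1056]]}
  - {name: R5, segments: [[1057, 1203]]}
  - {name: R6, segments: [[1204, 1351]]}
  - {name: R7, segments: [[1352, 1457], [1585, 1659]]}
  - {name: R8, segments: [[1458, 1584]]}
  - {name: R9, segments: [[1660, 1822]]}
  - {name: R10, segments: [[1823, 1974]]}
  - {name: R11, segments: [[1975, 2140]]}
  - {name: R12, segments: [[2141, 2299]]}
  - {name: R13, segments: [[2300, 2493]]}
  - {name: DD, segments: [[2494, 2541]]}
binding_sites:
  # membrane-anchoring / integrin-activation helix of F3
  - {name: integrin, host_domain: F3, residues: [[385, 405]]}
  # DLC-1 LD-motif contacts in R8
  - {name: DLC-1, host_domain: R8, residues: [1530, 1544]}
  # autoinhibition surface of R9 (around E1770)
  - {name: autoinhibition, host_domain: R9, residues: [[1762, 1772]]}
  # C-terminal actin-binding site spanning R13-DD (no single host domain)
  - {name: ABS3, residues: [[2300, 2541]]}
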