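# Sensor-to-place assignment for the CASAS HH120 single-resident testbed.
# M011 is listed under both P1 and P5 in the source assignment (an apparent
# typo); on_duplicate: first keeps it in P1 and warns, so event counts remain
# conserved across places.
on_duplicate: first
places:
  P1: [M009, M010, M011, MA016]
  P2: [M008, M018]
  P3: [MA017]
  P4: [M003, M004, M005, M006, M007, M026, MA015]
  P5: [D002, D004, M001, M002, M011]
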