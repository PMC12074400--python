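# Sensor-to-place assignment for the CASAS Aruba single-resident testbed.
# Five behaviorally meaningful places; Mxxx are PIR motion detectors,
# Dxxx are magnetic door contacts.
places:
  P1: [M001, M002, M003, M005, M006, M007, M023, M024]
  P2: [M004, M029, M031]
  P3: [M014, M015, M017, M018, M019]
  P4: [M009, M010, M012, M013, M025, M026, M027, M028]
  P5: [D001, D002, D003, D004, M008, M011, M021, M022, M030]
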