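# Synthetic stand-in for a J34-sized four-way junction (four 34-nt
# strands, 17-bp arms).  The strand halves are mutually complementary
# under the arm pairing scheme XR/RB/BH/HX; base identities are
# otherwise arbitrary (generated by junctionlab.topology.
# synthetic_junction_sequences with seed 20160314) because the
# analyses depend only on the topology.
arm_length: 17
strands:
  X: GGCCTCAATATAGAAGAAGATCGAAGAATACGAG
  R: CTCGTATTCTTCGATCTGATTGGCTGAGAACCTT
  B: AAGGTTCTCAGCCAATCCGCGATAGGAGGGCCAT
  H: ATGGCCCTCCTATCGCGTCTTCTATATTGAGGCC
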