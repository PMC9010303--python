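# Role-map template for a deposited nucleosome-stack model (mmCIF/PDB).
#
# Chain naming differs between depositions, so roles are never guessed:
# open the model in a viewer (or list chains with gemmi) and fill in the
# chain ids below.  For a CENP-A nucleosome / CENP-N stack you expect,
# per nucleosome: 2 DNA chains, 2x (CENP-A or H3, H4, H2A, H2B), plus
# one chain per bridging CENP-N copy.
#
# Histone identity must be one of: H3, CENP-A, H4, H2A, H2B.
# flexible_bp_per_end marks terminal base pairs that are not stably
# wrapped (13 per end for a CENP-A nucleosome without a stabilizing
# factor; 0 when the factor clamps the DNA ends).

nucleosomes:
  - id: N1
    dna: [I, J]           # <- replace with the model's DNA chain ids
    histones:
      A: CENP-A
      B: H4
      C: H2A
      D: H2B
      E: CENP-A
      F: H4
      G: H2A
      H: H2B
    flexible_bp_per_end: 0
    flexible: false
  # repeat for N2 ... for stacks and arrays

factors:
  - id: F1
    chain: K              # <- CENP-N chain id
    label: CENP-N
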