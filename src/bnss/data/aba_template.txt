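# ABA stomatal-closure network -- TRANSCRIPTION TEMPLATE (INCOMPLETE)
#
# This file is a scaffold for the 43-node guard-cell ABA signaling model.
# The Boolean rule table is NOT bundled with this package: it must be
# transcribed by the user from the published source model (Li / Assmann /
# Albert, the model this analysis tool was exercised on).  Any completed
# version of this file is therefore a USER TRANSCRIPTION, not a package
# artifact, and the user is responsible for its fidelity -- including
# deciding which nodes besides GCR1 (if any) are free (RANDOM) nodes.
#
# Conventions:
#   Name = expr           Boolean rule (operators AND / OR / NOT, parens)
#   Name = RANDOM         free node: fresh Bernoulli(1/2) value per update
#   clamp Name = True     hold a node fixed (hormone input / mutants)
#
# Node names that appear in the analyses this template supports (the full
# model has 43 nodes; add the remaining ones in declaration order):
#
#   ABA  S1P  PA  ABI1  pHc  NOS  NO  GCR1  GPA1  PLC  InsP3  CIS
#   Ca2+_c  Ca2+ATPase  KAP  KEV  KOUT  AnionEm  closure  ...
#
# Typical usage once transcribed:
#   - hormone signaling:   clamp ABA = True
#   - free node:           GCR1 = RANDOM
#   - mutants (CLI --mutate or apply_clamp): hold S1P / PA / ABI1 / pHc /
#     NOS in the False state.
#
# Example stanza (replace with the real transcribed rules):
#   GCR1 = RANDOM
#   GPA1 = S1P AND NOT GCR1        # <- transcribe actual rule
#   closure = ...                  # <- transcribe actual rule
#   clamp ABA = True
#
# The file is intentionally left without any active rule so that it fails
# validation until the transcription is complete.
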