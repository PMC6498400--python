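"""Joint-distribution-entropy coupling of two channels.

Builds two tiny epoched recordings — one whose two channels share a single
band-limited source, one whose channels are driven independently — runs the
preprocessing chain (trim, epoch-average, 9-34 Hz zero-phase band-pass,
unit-range rescale) and prints the pairwise JDistEn coupling for each.
"""

import numpy as np

from jdnet import CohortSpec, SourceModel, coupling_matrix, generate_subject, preprocess_subject

spec = CohortSpec(epoch_len=115, prestim=15)

shared = SourceModel(
    freqs=np.array([18.0]),
    mixing=np.array([[1.0], [1.0]]),  # both channels see the same oscillator
    noise_sd=0.1,
    modules=np.array([0, 0]),
)
independent = SourceModel(
    freqs=np.array([14.0, 26.0]),
    mixing=np.eye(2),  # one private oscillator per channel
    noise_sd=0.1,
    modules=np.array([0, 1]),
)

for name, model in (("shared source", shared), ("independent sources", independent)):
    rec = generate_subject(model, spec, subject_seed=42)
    w = coupling_matrix(preprocess_subject(rec))
    print(f"{name:20s} JDistEn = {w[0, 1]:.4f}")

print(
    "\nJDistEn lies in [0, 1]: channels sharing a stimulus-locked source keep"
    "\nthe full spread of their joint-distance histogram (value near 1), while"
    "\nindependent channels concentrate it (lower value)."
)
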