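"""Classify quality lines by k-mer repetition and look at the feature.

Each line's feature Mx is its summed distinct-k-mer sample proportion,
normalised by the in-sample maximum and clamped to 1.  Lines with
Mx > alpha go to class A (high repetition, compresses well); the rest to
class B.
"""

from qsarc import ClassifierParams, classify_stream, synthgen

lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=2_000, seed=3))
params = ClassifierParams(k=4, M=1_000, alpha=0.5)
labelled = classify_stream(lines, params)

mx = [f.mx for _, f in labelled]
n_a = sum(1 for _, f in labelled if f.label == "A")
print(f"lines:               {len(labelled)}")
print(f"in-sample max Mx:    {max(mx[:1000]):.3f}  (always exactly 1)")
print(f"feature range:       [{min(mx):.3f}, {max(mx):.3f}]")
print(f"class A / class B:   {n_a} / {len(labelled) - n_a}  (alpha = {params.alpha})")
print(f"fitted normaliser:   L_m = {params.L_m:.4f}")
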