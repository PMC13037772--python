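"""Simulate a small canine cfDNA cohort with known truth.

Writes a reference FASTA, per-sample fragment tables, qPCR Cq read-outs, a
sample sheet, and a truth table into ./example_cohort, then prints the truth:
each cancer subject's tumor fraction and the noise-free short index its
plasma would give.
"""

from cffrag.synthetic_cohort import generate_cohort

info = generate_cohort("example_cohort", n_healthy=4, n_cancer=4,
                       samples_per_subject=2, depth=300, seed=7)

print(info["truth"].to_string(index=False))
print()
print("tumor_fraction is 0 for healthy dogs by construction;")
print("true_short_index is the qPCR short index implied by each subject's")
print("fragment-length distribution before any measurement noise.")
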