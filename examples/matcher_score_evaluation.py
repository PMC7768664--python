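"""Evaluate matcher score lists: improvement ratio, EER, and FMR1000.

The package does not bundle a fingerprint matcher; external engines export
genuine/impostor similarity scores, which are evaluated here. Synthetic
normal score distributions stand in for such an export.
"""

import numpy as np

from bezridge import ScoreSet, ScoreTriple, eer_fmr, improvement_ratio

rng = np.random.default_rng(0)

# per-sample score triples: fractured, restored, ideal
triples = [ScoreTriple(*sorted(rng.uniform(100, 400, 3))) for _ in range(5)]
ratios = [improvement_ratio(t) for t in triples]
print("improvement ratios r = (S_restore - S_frac) / (S_ideal - S_frac):")
for t, r in zip(triples, ratios):
    print(f"  frac={t.s_frac:6.1f} restore={t.s_restore:6.1f} "
          f"ideal={t.s_ideal:6.1f} -> r={r:.3f}")

# verification error rates before/after a simulated restoration gain
before = ScoreSet(genuine=rng.normal(1.2, 1.0, 4000),
                  impostor=rng.normal(0.0, 1.0, 4000))
after = ScoreSet(genuine=rng.normal(2.0, 1.0, 4000),
                 impostor=rng.normal(0.0, 1.0, 4000))
for label, ss in (("without restoration", before), ("with restoration", after)):
    eer, fmr1000, _, _ = eer_fmr(ss)
    print(f"{label:20s} EER = {100 * eer:5.2f}%   FNMR@FMR<=0.1% = "
          f"{100 * fmr1000:5.2f}%")
print()
print("Raising the genuine-score distribution (better restored images)")
print("lowers both the equal error rate and the FMR1000 operating point.")
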