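"""Recompute published benchmark metrics from confusion-matrix counts.

The package ships the confusion matrices of a multimodal sleep-staging
benchmark (Sleep-EDF-20/78, SHHS, and an OSA clinical cohort).  The metric
suite rederives every printed summary statistic from the raw counts.
"""

from somnostage.metrics import overall_metrics, round_half_up
from somnostage.reference import REFERENCE_CONFUSIONS

print(f"{'dataset':14s} {'ACC':>6s} {'MF1':>6s} {'kappa':>6s}")
for name, cm in REFERENCE_CONFUSIONS.items():
    r = overall_metrics(cm)
    print(f"{name:14s} {round_half_up(r.acc):6.1f} {round_half_up(r.mf1):6.1f} "
          f"{round_half_up(r.kappa):6.1f}")

# ACC = trace/total; MF1 = unweighted mean of the five per-class F1 scores;
# kappa = chance-corrected agreement, reported x100.  The OSA cohort scores
# lower across the board -- fragmented sleep makes staging genuinely harder.
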