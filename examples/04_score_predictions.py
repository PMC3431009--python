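"""The hierarchical competition scoring rule and diagnostic metrics.

Scores a small hand-made prediction set: exact matches earn 1 point,
a correct ADHD diagnosis with the wrong subtype earns 0.5, everything
else 0.  Also prints the collapsed binary metrics (sensitivity,
specificity, Youden's J) and the conditional subtype accuracy.
"""

from adhdconn import score_report

truth = ["TD", "INATTENTIVE", "HYPERACTIVE", "COMBINED", "TD", "COMBINED"]
pred = ["TD", "COMBINED", "HYPERACTIVE", "TD", "COMBINED", "COMBINED"]

report = score_report(truth, pred)
print(f"points                      : {report.points} of {report.n}")
print(f"competition accuracy        : {report.percent:.1f}%")
print(f"sensitivity (ADHD detected) : {report.sensitivity:.2f}")
print(f"specificity (TD preserved)  : {report.specificity:.2f}")
print(f"Youden's J                  : {report.youden_j:.2f}")
print(f"subtype accuracy | detected : {report.conditional_subtype_accuracy:.2f}")
print(
    "\nsubject 2 earns 0.5 (right diagnosis, wrong subtype); subject 4\n"
    "earns 0 (ADHD called TD); J = sensitivity + specificity - 1"
)
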