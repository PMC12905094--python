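"""Classify per-target SUV changes and summarize cohort response rates.

Takes hand-written pre/post SUV_mean values for a small cohort, computes
the relative difference of each, classifies it under the +15%/+30%
thresholds, and prints the rounded cohort rates.
"""

from petresponse import classify, relative_difference, round_rate

# (target id, baseline SUV_mean, follow-up SUV_mean)
cohort = [
    (1, 8.4, 4.1),
    (2, 12.0, 7.1),
    (3, 6.2, 6.5),
    (4, 9.8, 11.8),   # +20.4% -> indeterminate
    (5, 7.5, 10.9),   # +45.3% -> progression
    (6, 10.3, 5.9),
    (7, 5.1, 5.0),
    (8, 11.6, 12.9),  # +11.2% -> still response (<= +15%)
]

counts = {"response": 0, "indeterminate": 0, "progression": 0}
print("target  pre    post   RD%      category")
for tid, pre, post in cohort:
    rd = relative_difference(pre, post)
    cat = classify(rd)
    counts[cat] += 1
    print(f"{tid:>6}  {pre:5.1f}  {post:5.1f}  {rd:+7.1f}  {cat}")

n = len(cohort)
print(f"\nof {n} targets:")
for cat, c in counts.items():
    print(f"  {cat:>13}: {c}  ({round_rate(c, n):.1f}%)")
print(
    "\nAny increase of at most 15% (including every decrease) counts as a"
    "\nresponse; at least 30% counts as progression; the open interval"
    "\nbetween is indeterminate.  Rates use half-to-even rounding at one"
    "\ndecimal, so 1/16 prints as 6.2, not 6.3."
)
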