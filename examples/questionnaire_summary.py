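"""Summarise satisfaction-questionnaire responses.

Counts and half-up-rounded proportions; satisfaction is the share of
respondents answering in the designated top levels.
"""
import pandas as pd

import childcheck as cc

responses = pd.DataFrame({
    "satisfaction": ["Very satisfied"] * 10 + ["Extremely satisfied"] * 2
                    + ["Somewhat satisfied"] * 2
})
summary = cc.summarize_questionnaire(
    responses,
    scale=["Somewhat satisfied", "Very satisfied", "Extremely satisfied"],
    satisfied_levels={"Very satisfied", "Extremely satisfied"},
)
print(f"respondents:   {summary.n_respondents}")
print(f"satisfaction:  {summary.satisfaction_percent}% (n={summary.satisfaction_count})")

breakdown = cc.categorical_summary(["healthy"] + ["overweight"] * 5 + ["obese"] * 8)
for level, row in breakdown.items():
    print(f"{level:12s} {row['percent']:5.1f}% ({row['count']})")
# 12 of 14 satisfied -> 86%; categorical breakdowns use one-decimal percents.
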