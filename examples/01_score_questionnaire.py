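"""Score a small respondent file with the built-in 18-item knee instrument.

Builds a 5-row CSV in memory (one respondent with a missing answer), applies
complete-case filtering and the 0-100 transform, and shows the
mean-substitution scoring variant for near-complete rows.
"""

import tempfile
from pathlib import Path

import numpy as np

import promstruct as ps

ikdc = ps.builtin_ikdc()
rng = np.random.default_rng(0)

codes = np.column_stack(
    [rng.integers(0, ikdc.item(i).n_categories, 5) for i in ikdc.scored_item_ids]
)
rows = [",".join(map(str, r)) for r in codes]
rows[2] = "," + rows[2].split(",", 1)[1]  # respondent 2 skipped item 1

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "responses.csv"
    path.write_text(",".join(ikdc.scored_item_ids) + "\n" + "\n".join(rows) + "\n")
    data = ps.read_responses(path, ikdc)

complete, summary = ps.complete_case_filter(data, ikdc)
print(f"{summary.n_complete}/{summary.n_total} complete rows "
      f"({summary.pct_complete_rounded}%)")

scores = ps.total_score(data, ikdc)
partial = ps.total_score(data, ikdc, allow_partial=True)
for rid, strict, lenient in zip(data.respondent_ids, scores, partial):
    print(f"respondent {rid}: complete-case score = {strict:6.2f}   "
          f"mean-substitution score = {lenient:6.2f}")
print("Scores run 0 (worst) to 100 (best); the respondent with a skipped item "
      "is NaN under complete-case scoring but scored by mean substitution "
      "because 17 of 18 items were answered.")
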