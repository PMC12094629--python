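"""Demographic comparison statistics for the emulated study's groups.

Recomputes the group-comparison statistics from the published demographic
counts and summaries: gender and handedness 2x2 tables (chi-square with
Yates continuity correction) and age (pooled two-sample t from the printed
means and SDs).  None approaches significance, consistent with the groups
being demographically matched.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort_cache import RESULTS  # noqa: E402

from eegsync.stats import (  # noqa: E402
    ContingencyTable2x2, chi_square_yates, summary_t,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    gender = ContingencyTable2x2(23, 27, 21, 21)   # HC m/f, IA m/f
    hand = ContingencyTable2x2(47, 3, 41, 1)       # HC r/l, IA r/l
    g_chi2, g_p = chi_square_yates(gender)
    h_chi2, h_p = chi_square_yates(hand)
    a_t, a_p = summary_t(20.56, 1.57, 50, 20.71, 1.50, 42)

    print("group comparisons (42 IA vs 50 HC):")
    print(f"  gender     chi2 = {g_chi2:.2f}, p = {g_p:.3f}")
    print(f"  handedness chi2 = {h_chi2:.3f}, p = {h_p:.3f}")
    print(f"  age        |t|  = {abs(a_t):.2f}, p = {a_p:.3f}")

    out = RESULTS / "cohort_stats.json"
    out.write_text(json.dumps({
        "gender": {"chi2": g_chi2, "p": g_p, "yates": True},
        "handedness": {"chi2": h_chi2, "p": h_p, "yates": True},
        "age": {"t": a_t, "p": a_p, "df": 90},
    }, indent=2))
    print(f"results -> {out}")


if __name__ == "__main__":
    main()
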