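"""Screen connections by group t-test and map electrode engagement.

For each metric (PLI, WPLI), every (band, channel-pair) connection is
tested for an IA-HC group difference (two-sample t, p < 0.05, uncorrected,
as in the reproduced pipeline), and each electrode's count of significant
connections is tallied per band.  Expected pattern: selected connections
concentrate in the delta band over frontal electrodes and the gamma bands
over occipital electrodes, with IA > HC.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort_cache import RESULTS, get_cohort  # noqa: E402

from eegsync.features import engagement_map, select_features  # noqa: E402


def main() -> None:
    config, tensors, labels = get_cohort()
    for name, tensor in tensors.items():
        mask = select_features(tensor, labels, alpha=0.05)
        mask_df = mask.to_dataframe()
        mask_df.to_csv(RESULTS / f"feature_mask_{name}.csv", index=False,
                       float_format="%.5g")
        em = engagement_map(mask, tensor.channel_labels, tensor.band_names)
        em.to_csv(RESULTS / f"engagement_map_{name}.csv")

        n_up = int((mask_df.direction == "IA>HC").sum())
        print(f"\n{name.upper()}: {len(mask)} of {tensor.n_features} "
              f"connections significant at p<0.05 "
              f"({n_up} stronger in IA)")
        by_band = mask_df.groupby("band").size()
        print("  per band:", dict(by_band))
        top_elec = em.sum(axis=0).sort_values(ascending=False).head(5)
        print("  most engaged electrodes:", dict(top_elec))
    print(f"\nmasks and engagement maps -> {RESULTS}")


if __name__ == "__main__":
    main()
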