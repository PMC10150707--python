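"""Per-site differential hydroxymethylation: NSC vs iPSC paired contrast.

Classical paired t-tests on the normalized values, BH FDR, volcano
classification, the direction summary (global hypo-hydroxymethylation
signature), and the moderated-t comparison.  Checks recovery of the planted
truth: affected sites should dominate the top of the ranking.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hydroxyscan.diff import diff_table, moderated_paired_t, summarize_direction
from hydroxyscan.samples import paired_samples, read_sample_sheet

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    norm = pd.read_csv(DATA / "normalized.tsv", sep="\t", index_col=0)
    sheet = read_sample_sheet(DATA / "samples.tsv")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", index_col=0, keep_default_na=False)
    truth["affected"] = truth["affected"].astype(str) == "True"

    pairs = paired_samples(sheet, "subject", ("NSC", "iPSC"))
    res = diff_table(norm, pairs, contrast_label="NSC vs iPSC")
    res.rename_axis("site").to_csv(DATA / "diff.tsv", sep="\t")

    summary = summarize_direction(res)
    pd.Series(summary).rename("value").rename_axis("statistic").to_csv(
        RESULTS / "direction_summary.tsv", sep="\t"
    )
    print("direction summary (negative FC = NSC hypo-hydroxymethylation):")
    for k, v in summary.items():
        print(f"  {k}: {v}")

    top = res.sort_values("p_value").head(10)
    top.join(truth[["affected", "site_effect"]]).rename_axis("site").to_csv(
        RESULTS / "top_sites.tsv", sep="\t"
    )
    frac_true = truth.loc[top.index, "affected"].mean()
    print(f"top-10 sites: {frac_true:.0%} are planted non-null sites")

    mod, prior = moderated_paired_t(norm, pairs)
    agree = np.corrcoef(np.abs(mod["t"]), np.abs(mod["t_mod"]))[0, 1]
    print(f"moderated t: prior d0={prior.d0:.2f}, s0^2={prior.s0_sq:.4f}; "
          f"|t| correlation with classical = {agree:.3f}")


if __name__ == "__main__":
    main()
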