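"""Sample metadata: one row per sequencing library.

Required columns: sample, subject, cell_type, group, pair, age, sex.  The
paired design has one library per (subject, cell type); disease pairs tie a
case to its matched unaffected sibling.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ["sample", "subject", "cell_type", "group", "pair", "age", "sex"]


class SampleSheetError(ValueError):
    pass


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"sample sheet missing columns: {missing}")
    df["age"] = df["age"].astype(float)
    return df


def validate_sample_sheet(df: pd.DataFrame) -> list[str]:
    """Return a list of human-readable failures (empty when clean)."""
    failures: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        failures.append(f"missing columns: {missing}")
        return failures
    if df["sample"].duplicated().any():
        dup = sorted(df.loc[df["sample"].duplicated(), "sample"])
        failures.append(f"duplicate sample identifiers: {dup}")
    for (subject, ct), sub in df.groupby(["subject", "cell_type"]):
        if len(sub) > 1:
            failures.append(f"subject {subject!r} has {len(sub)} {ct!r} samples (expected 1)")
    for subject, sub in df.groupby("subject"):
        if sub["pair"].nunique() > 1:
            failures.append(f"subject {subject!r} assigned to multiple pairs")
    for pair, sub in df.groupby("pair"):
        subjects = sub.drop_duplicates("subject")
        if len(subjects) != 2:
            failures.append(f"pair {pair!r} has {len(subjects)} subjects (expected 2)")
        elif set(subjects["group"]) != set(subjects["group"]) or subjects["group"].nunique() != 2:
            failures.append(f"pair {pair!r} does not pair two distinct disease groups")
    return failures


def paired_samples(
    df: pd.DataFrame, pair_by: str, contrast: tuple[str, str], within: dict | None = None
) -> list[tuple[str, str]]:
    """Build (sample_A, sample_B) pairs for a paired contrast B vs A.

    ``pair_by`` is the column whose value ties the two members together
    (``subject`` for the cell-type contrast, ``pair`` for the disease
    contrast); ``contrast`` is (group_B, group_A) over either ``cell_type``
    or ``group``; ``within`` optionally restricts rows first
    (e.g. ``{"cell_type": "NSC"}``).
    """
    sub = df
    if within:
        for col, val in within.items():
            sub = sub[sub[col] == val]
    b_label, a_label = contrast
    col = "cell_type" if b_label in set(sub["cell_type"]) else "group"
    pairs = []
    for key, grp in sub.groupby(pair_by):
        a = grp.loc[grp[col] == a_label, "sample"]
        b = grp.loc[grp[col] == b_label, "sample"]
        if len(a) != 1 or len(b) != 1:
            raise SampleSheetError(
                f"{pair_by}={key!r}: expected exactly one {a_label!r} and one {b_label!r} sample"
            )
        pairs.append((a.iloc[0], b.iloc[0]))
    if len(pairs) < 2:
        raise SampleSheetError("need at least two pairs")
    return pairs
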