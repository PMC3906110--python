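"""Mining unannotated reads for candidate novel miRNAs.

A previously unknown miRNA able to compete for Argonaute occupancy would have
to be reasonably abundant; the screen therefore flags unannotated
genome-matching sequences of canonical mature length (21-23 nt) whose
abundance exceeds 200 reads per million miRNA reads (0.02% of total miRNA)
in any sample.  The comparison is strictly greater-than, and the denominator
is miRNA reads, not all reads.
"""

from __future__ import annotations

import warnings

import pandas as pd

MIN_CANDIDATE_LEN = 21
MAX_CANDIDATE_LEN = 23
DEFAULT_THRESHOLD_RPM = 200.0


def mine_candidates(
    unannotated: pd.DataFrame,
    mirna_totals: pd.Series,
    threshold_rpm: float = DEFAULT_THRESHOLD_RPM,
) -> pd.DataFrame:
    """Screen unannotated genome-matching reads for abundant candidates.

    Parameters
    ----------
    unannotated : DataFrame
        Columns ``sequence, sample, count`` (from the annotation stage's
        unannotated-genomic class); candidates are collapsed by exact
        sequence identity.
    mirna_totals : Series
        Total miRNA reads per sample (the RPM denominator).
    threshold_rpm : float, default 200
        Flag when the per-sample maximum RPM strictly exceeds this.

    Returns
    -------
    DataFrame indexed by sequence with ``length``, one ``rpm_<sample>``
    column per usable sample, ``max_rpm`` and ``flag``.
    """
    usable = mirna_totals[mirna_totals > 0]
    dropped = set(mirna_totals.index) - set(usable.index)
    if dropped:
        warnings.warn(
            f"sample(s) with zero miRNA total excluded from mining: {sorted(dropped)}",
            stacklevel=2,
        )
    cols = [f"rpm_{s}" for s in usable.index]
    if unannotated.empty:
        return pd.DataFrame(columns=["length", *cols, "max_rpm", "flag"])

    sub = unannotated[
        unannotated["sequence"].str.len().between(MIN_CANDIDATE_LEN, MAX_CANDIDATE_LEN)
        & unannotated["sample"].isin(usable.index)
    ]
    if sub.empty:
        return pd.DataFrame(columns=["length", *cols, "max_rpm", "flag"])

    pivot = (
        sub.pivot_table(index="sequence", columns="sample", values="count", aggfunc="sum")
        .reindex(columns=usable.index)
        .fillna(0.0)
    )
    rpm = pivot.div(usable, axis=1) * 1e6
    report = pd.DataFrame(index=rpm.index)
    report["length"] = [len(s) for s in rpm.index]
    for s in usable.index:
        report[f"rpm_{s}"] = rpm[s]
    report["max_rpm"] = rpm.max(axis=1)
    report["flag"] = report["max_rpm"] > threshold_rpm
    return report.sort_values("max_rpm", ascending=False)
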