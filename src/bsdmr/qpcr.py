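"""Relative transcript quantification by the comparative Ct (Livak) method.

Per sample, dCt = mean Ct(target) - mean Ct(reference gene); ddCt subtracts
the reference group's mean dCt, and the fold change is 2**(-ddCt): one cycle
less for the target means twice the transcript.  Technical replicates are
averaged at the Ct level before dCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GROUPS

PLATE_COLUMNS = ["sample_id", "group", "gene", "ct"]


@dataclass
class QpcrPlate:
    """Long-format qPCR measurements: sample_id, group, gene, ct (+ optional replicate)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate table missing column(s): {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.data["group"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")


def read_qpcr_plate(path) -> QpcrPlate:
    return QpcrPlate(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                        "group": str, "gene": str}))


@dataclass
class DdctResult:
    per_sample: pd.DataFrame   # sample_id, group, dct, ddct, fold
    per_group: pd.DataFrame    # group, fold_mean, fold_sem, fold_from_mean_dct, n

    @property
    def treatment_fold(self) -> float:
        row = self.per_group.set_index("group")
        return float(row.loc["treatment", "fold_from_mean_dct"])


def ddct_fold_change(plate: QpcrPlate, target_gene: str,
                     reference_gene: str = "ef1a") -> DdctResult:
    """2^-ddCt fold changes of ``target_gene`` normalized to ``reference_gene``.

    Raises if any sample lacks a reference-gene measurement or the reference
    group is empty.
    """
    df = plate.data
    mean_ct = (df.groupby(["sample_id", "group", "gene"], as_index=False)["ct"]
                 .mean())
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample_id")
    tgt = mean_ct[mean_ct["gene"] == target_gene].set_index("sample_id")
    if tgt.empty:
        raise ValueError(f"no measurements for target gene {target_gene!r}")
    missing = sorted(set(tgt.index) - set(ref.index))
    if missing:
        raise ValueError(
            f"sample(s) missing reference gene {reference_gene!r}: {missing}")

    per = pd.DataFrame({
        "sample_id": tgt.index,
        "group": tgt["group"].to_numpy(),
        "dct": tgt["ct"].to_numpy() - ref.loc[tgt.index, "ct"].to_numpy(),
    })
    ref_rows = per[per["group"] == "reference"]
    if ref_rows.empty:
        raise ValueError("reference group is empty")
    anchor = ref_rows["dct"].mean()
    per["ddct"] = per["dct"] - anchor
    per["fold"] = 2.0 ** (-per["ddct"])
    per = per.sort_values(["group", "sample_id"]).reset_index(drop=True)

    groups = []
    for group, sub in per.groupby("group", sort=True):
        folds = sub["fold"].to_numpy()
        sem = folds.std(ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else 0.0
        groups.append({
            "group": group,
            "fold_mean": float(folds.mean()),
            "fold_sem": float(sem),
            # anchor-normalized: exactly 1.0 for the reference group
            "fold_from_mean_dct": float(2.0 ** (-(sub["dct"].mean() - anchor))),
            "n": len(folds),
        })
    return DdctResult(per_sample=per, per_group=pd.DataFrame(groups))
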