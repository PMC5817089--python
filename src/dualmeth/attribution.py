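"""Dual-assay attribution: resolve loci significant in the composite
(5mC + 5hmC, bisulfite) and/or 5hmC (TAB) analyses into DML vs DhML calls
and split them by species direction.

A locus significant in both assays carries its differential signal in the
5hmC component (the composite shifts because its hydroxymethyl part does),
so dual-significant loci are classed DhML unconditionally; loci significant
only in the composite assay are DML, only in the TAB assay DhML.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

QUADRANTS = {
    (1, 1): "human_human",
    (-1, -1): "monkey_monkey",
    (1, -1): "human_monkey",
    (-1, 1): "monkey_human",
}


def mean_delta(betas: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Per-probe human mean minus monkey mean (available-case means).

    Positive values mean more signal in humans.  A probe with one species
    entirely missing gets a missing delta.
    """
    sheet = sheet.set_index("sample_id")
    idx = sheet.loc[list(betas.columns), "species"]
    human = betas.loc[:, (idx == "human").to_numpy()]
    monkey = betas.loc[:, (idx == "monkey").to_numpy()]
    if human.shape[1] == 0 or monkey.shape[1] == 0:
        raise ValueError("both species must be present in the matrix")
    return human.mean(axis=1, skipna=True) - monkey.mean(axis=1, skipna=True)


def attribute_dual_loci(
    dml_ids,
    dhml_ids,
    delta_composite: pd.Series,
    delta_hmc: pd.Series,
    concordance_tol: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Class every significant locus as DML or DhML.

    ``dml_ids`` are loci significant in the composite (BS) analysis,
    ``dhml_ids`` in the 5hmC (TAB) analysis.  Dual-significant loci become
    DhML with a quadrant label from the sign pair (composite, 5hmC); the
    second return value is the fraction of dual loci whose two deltas agree
    in sign and differ by at most ``concordance_tol`` ("similar
    abundances"), NaN when there are no dual loci.
    """
    dml_ids, dhml_ids = set(dml_ids), set(dhml_ids)
    dual = dml_ids & dhml_ids
    missing = [
        pid
        for pid in dual
        if pid not in delta_composite.index
        or pid not in delta_hmc.index
        or pd.isna(delta_composite.get(pid))
        or pd.isna(delta_hmc.get(pid))
    ]
    if missing:
        raise ValueError(f"dual-significant loci lacking a delta: {sorted(missing)[:5]}")

    records = []
    for pid in sorted(dml_ids | dhml_ids):
        dc = delta_composite.get(pid, np.nan)
        dh = delta_hmc.get(pid, np.nan)
        is_dual = pid in dual
        final = "DhML" if (is_dual or pid in dhml_ids) else "DML"
        quadrant = None
        if is_dual:
            quadrant = QUADRANTS.get(
                (1 if dc > 0 else -1, 1 if dh > 0 else -1)
            )
        rel = dh if final == "DhML" and pid in dhml_ids else dc
        direction = "human_specific" if rel > 0 else "monkey_specific"
        records.append(
            {
                "probe_id": pid,
                "delta_composite": dc,
                "delta_hmc": dh,
                "final_class": final,
                "quadrant": quadrant,
                "direction": direction,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("probe_id") if records else (
        pd.DataFrame(
            columns=[
                "delta_composite",
                "delta_hmc",
                "final_class",
                "quadrant",
                "direction",
            ]
        )
    )
    if dual:
        dc = delta_composite.loc[sorted(dual)].to_numpy()
        dh = delta_hmc.loc[sorted(dual)].to_numpy()
        concordant = (np.sign(dc) == np.sign(dh)) & (np.abs(dc - dh) <= concordance_tol)
        concordance = float(concordant.mean())
    else:
        concordance = float("nan")
    return table, concordance


def split_by_direction(calls: pd.DataFrame, delta_col: str = "delta_beta"):
    """Partition significant loci by the sign of their delta.

    ``calls`` is indexed by probe with a signed delta column (and, when
    present, a boolean ``significant`` column restricting the split).
    Returns (human_specific ids, monkey_specific ids).
    """
    df = calls
    if "significant" in df.columns:
        df = df[df["significant"].astype(bool)]
    delta = df[delta_col]
    zero = delta == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} significant loci with delta exactly 0 assigned no direction"
        )
    human = set(df.index[delta > 0])
    monkey = set(df.index[delta < 0])
    return human, monkey
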