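"""Replicate averaging, detection-p masking, missingness filtering, genomic
structure profiles and unsupervised sample clustering."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import validate_sample_sheet


def mask_by_detection_p(
    betas: pd.DataFrame, detp: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Set entries missing where the detection p-value strictly exceeds the
    threshold; an entry exactly at the threshold is retained."""
    if betas.shape != detp.shape:
        raise ValueError(
            f"beta {betas.shape} and detection-p {detp.shape} shapes differ"
        )
    detp = detp.reindex(index=betas.index, columns=betas.columns)
    return betas.mask(detp > threshold)


def average_technical_replicates(
    betas: pd.DataFrame, sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse technical-replicate columns to their per-probe mean.

    The mean is over non-missing members, so a pair with one missing value
    keeps the available measurement; an all-missing pair stays missing.
    Returns the collapsed matrix (one column per replicate group, in first-
    appearance order) and the collapsed sample sheet.
    """
    sheet = validate_sample_sheet(sheet)
    sheet = sheet[sheet["sample_id"].isin(betas.columns)]
    group_of = dict(zip(sheet["sample_id"], sheet["replicate_group"]))
    groups: list[str] = []
    for s in betas.columns:
        g = group_of.get(s, s)
        if g not in groups:
            groups.append(g)
    cols = {}
    for g in groups:
        members = [s for s in betas.columns if group_of.get(s, s) == g]
        cols[g] = betas[members].mean(axis=1, skipna=True)
    collapsed = pd.DataFrame(cols, index=betas.index)
    new_sheet = (
        sheet.drop_duplicates("replicate_group")
        .assign(sample_id=lambda d: d["replicate_group"])
        .reset_index(drop=True)
    )
    new_sheet = new_sheet.set_index("sample_id").loc[groups].reset_index()
    return collapsed, new_sheet[sheet.columns.tolist()]


def filter_missingness(betas: pd.DataFrame, max_missing: int = 1) -> pd.DataFrame:
    """Keep a probe iff at most ``max_missing`` of its samples are missing."""
    keep = betas.isna().sum(axis=1) <= max_missing
    return betas.loc[keep]


def structure_profile(
    betas: pd.DataFrame, annotation: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Mean beta per species for each genomic-structure / island label.

    For each probe the per-species mean beta (over available samples) is
    computed first; a probe annotated with k distinct region groups then
    contributes that value once to each of the k label means.  Intergenic
    probes contribute to an ``intergenic`` label; island relations are
    single-valued.  Returns columns species, label_type, label, mean_beta.
    """
    annotation = annotation.loc[annotation.index.intersection(betas.index)]
    betas = betas.loc[annotation.index]
    records = []
    for sp, sub in sheet.groupby("species"):
        samples = [s for s in sub["sample_id"] if s in betas.columns]
        if not samples:
            continue
        probe_mean = betas[samples].mean(axis=1, skipna=True)
        region_members: dict[str, list[float]] = {}
        island_members: dict[str, list[float]] = {}
        for pid, entries, island in zip(
            annotation.index, annotation["gene_entries"], annotation["island_relation"]
        ):
            v = probe_mean.loc[pid]
            labels = {g for _, g in entries} or {"intergenic"}
            for lab in labels:
                region_members.setdefault(lab, []).append(v)
            island_members.setdefault(island, []).append(v)
        for label_type, members in (("region", region_members), ("island", island_members)):
            for lab, vals in members.items():
                vals = np.asarray(vals, dtype=float)
                vals = vals[~np.isnan(vals)]
                if len(vals) == 0:
                    warnings.warn(f"label {lab!r} has no probes with data; omitted")
                    continue
                records.append(
                    {
                        "species": sp,
                        "label_type": label_type,
                        "label": lab,
                        "mean_beta": float(vals.mean()),
                        "n_probes": int(len(vals)),
                    }
                )
    return pd.DataFrame.from_records(records)


def cluster_samples(
    betas: pd.DataFrame,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of samples on complete probes.

    Probes with any missing value are excluded so distances are exact and
    deterministic.  Returns the scipy linkage matrix and the 2-cluster cut
    as a Series over sample ids (labels 1/2).
    """
    if betas.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    complete = betas.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no probes without missing values")
    X = complete.to_numpy().T
    Z = linkage(pdist(X, metric=metric), method=linkage_method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=betas.columns, name="cluster")


def preprocess_arm(
    betas: pd.DataFrame,
    detp: pd.DataFrame,
    sheet: pd.DataFrame,
    detection_threshold: float = 0.01,
    max_missing: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-arm preprocessing: mask, average replicates, filter.

    Returns the filtered matrix and its collapsed sample sheet.
    """
    masked = mask_by_detection_p(betas, detp, threshold=detection_threshold)
    collapsed, new_sheet = average_technical_replicates(masked, sheet)
    filtered = filter_missingness(collapsed, max_missing=max_missing)
    return filtered, new_sheet
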