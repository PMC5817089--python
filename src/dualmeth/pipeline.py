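"""End-to-end orchestration of one assay arm and of the dual-assay study.

One arm: preprocess (mask, average replicates, filter) -> factor-adjusted
per-probe species test -> genome-ordered HMM-LIS calling.  The dual-assay
run does both arms and resolves loci significant in both into DML/DhML
classes with direction splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import attribute_dual_loci, mean_delta, split_by_direction
from .diffmeth import ConfounderAdjustedTester
from .hmm import HmmLisFdr, order_and_clean
from .preprocess import preprocess_arm
from .simulate import SimulatedDataset


@dataclass
class ArmResult:
    """Per-arm differential results joined with HMM-LIS calls."""

    stats: pd.DataFrame  # chrom, pos, delta_beta, p_raw, z, lis, alis, significant, direction
    betas: pd.DataFrame
    sheet: pd.DataFrame
    tester: ConfounderAdjustedTester = field(repr=False)
    hmm: HmmLisFdr = field(repr=False)

    @property
    def significant_ids(self) -> set[str]:
        return set(self.stats.index[self.stats["significant"]])


def run_arm(
    betas: pd.DataFrame,
    detp: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    k_factors="auto",
    alpha: float = 0.01,
    detection_threshold: float = 0.01,
    random_state: int = 0,
    **hmm_kwargs,
) -> ArmResult:
    """Preprocess, test and call one assay arm."""
    filtered, arm_sheet = preprocess_arm(
        betas, detp, sheet, detection_threshold=detection_threshold
    )
    tester = ConfounderAdjustedTester(
        k_factors=k_factors, random_state=random_state
    ).fit(filtered, arm_sheet)
    stats = tester.results_.join(annotation[["chrom", "pos"]], how="left")
    ordered = order_and_clean(stats)

    hmm = HmmLisFdr(alpha=alpha, **hmm_kwargs).fit(
        ordered["z"].to_numpy(), ordered["chrom"].to_numpy()
    )
    ordered = ordered.assign(
        lis=hmm.lis_, alis=hmm.alis_, significant=hmm.significant_
    )
    ordered["direction"] = np.where(
        ~ordered["significant"],
        "none",
        np.where(ordered["delta_beta"] > 0, "human_specific", "monkey_specific"),
    )
    return ArmResult(
        stats=ordered, betas=filtered, sheet=arm_sheet, tester=tester, hmm=hmm
    )


@dataclass
class DualResult:
    bs: ArmResult
    tab: ArmResult
    attribution: pd.DataFrame
    concordance: float
    dml_ids: set
    dhml_ids: set
    human_dml: set
    monkey_dml: set
    human_dhml: set
    monkey_dhml: set


def run_dual_assay(
    dataset: SimulatedDataset | dict,
    k_factors="auto",
    alpha: float = 0.01,
    random_state: int = 0,
    **hmm_kwargs,
) -> DualResult:
    """Run both assay arms of a dataset and attribute dual calls.

    ``dataset`` is a :class:`SimulatedDataset` or a dict with the same
    field names (bs_betas, tab_betas, bs_detp, tab_detp, sheet, annotation).
    """
    d = dataset if isinstance(dataset, dict) else dataset.__dict__
    sheet = d["sheet"]
    bs = run_arm(
        d["bs_betas"],
        d["bs_detp"],
        sheet[sheet["assay"] == "BS"],
        d["annotation"],
        k_factors=k_factors,
        alpha=alpha,
        random_state=random_state,
        **hmm_kwargs,
    )
    tab = run_arm(
        d["tab_betas"],
        d["tab_detp"],
        sheet[sheet["assay"] == "TAB"],
        d["annotation"],
        k_factors=k_factors,
        alpha=alpha,
        random_state=random_state,
        **hmm_kwargs,
    )

    delta_composite = mean_delta(bs.betas, bs.sheet)
    delta_hmc = mean_delta(tab.betas, tab.sheet)
    table, concordance = attribute_dual_loci(
        bs.significant_ids, tab.significant_ids, delta_composite, delta_hmc
    )
    dml_ids = set(table.index[table["final_class"] == "DML"])
    dhml_ids = set(table.index[table["final_class"] == "DhML"])
    if len(table):
        dml_table = table[table["final_class"] == "DML"]
        dhml_table = table[table["final_class"] == "DhML"]
        human_dml, monkey_dml = split_by_direction(
            dml_table.assign(significant=True), delta_col="delta_composite"
        )
        human_dhml, monkey_dhml = split_by_direction(
            dhml_table.assign(significant=True), delta_col="delta_hmc"
        )
    else:
        human_dml = monkey_dml = human_dhml = monkey_dhml = set()
    return DualResult(
        bs=bs,
        tab=tab,
        attribution=table,
        concordance=concordance,
        dml_ids=dml_ids,
        dhml_ids=dhml_ids,
        human_dml=human_dml,
        monkey_dml=monkey_dml,
        human_dhml=human_dhml,
        monkey_dhml=monkey_dhml,
    )
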