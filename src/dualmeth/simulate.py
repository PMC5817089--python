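"""Synthetic two-species, dual-assay methylation-array generator.

Emulates the structure of a cross-species HM450 study: a bisulfite (BS) arm
measuring the composite 5mC + 5hmC signal and a TET-assisted bisulfite
(TAB) arm measuring 5hmC alone, with latent confounders, beadchip batches,
Markov-dependent differential states along each chromosome, technical
replicates in the TAB arm, and per-probe ground truth for recovery tests.

The generative model works on the logit scale.  Each probe carries a
baseline composite level (shaped by its genomic annotation: CpG islands and
TSS200 probes low, gene bodies / 3'UTRs and open sea high) split into a
methyl and a hydroxymethyl component; species effects at differential
probes shift one component only, so the TAB expectation never exceeds the
BS expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ISLAND_RELATIONS, REGION_GROUPS, validate_sample_sheet

_EPS = 1e-4

#: logit-scale baseline offsets by island relation (composite signal)
_ISLAND_BASE = {
    "Island": -2.2,
    "N_Shore": -0.6,
    "S_Shore": -0.6,
    "N_Shelf": 0.7,
    "S_Shelf": 0.7,
    "OpenSea": 1.3,
}
#: logit-scale adjustments by region group
_REGION_ADJUST = {
    "TSS1500": -0.7,
    "TSS200": -1.4,
    "5UTR": -0.5,
    "1stExon": -0.9,
    "Body": 0.4,
    "3UTR": 0.6,
}
#: sampling weights for region groups at genic probes
_REGION_WEIGHTS = {
    "TSS1500": 0.14,
    "TSS200": 0.12,
    "5UTR": 0.12,
    "1stExon": 0.08,
    "Body": 0.44,
    "3UTR": 0.10,
}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Sample sizes default to a small cross-species brain-tissue design:
    3 human vs 7 monkey for the BS arm, 6 human vs 11 monkey for the TAB
    arm, the latter run as technical replicate pairs.  ``state_transition`` drives the two-state
    (null / differential) Markov chain along probe order within each
    chromosome; the default stationary differential fraction is
    0.01 / (0.01 + 0.25) ~ 3.8%.  ``effect_size`` is the mean logit-scale
    species shift at differential probes and ``frac_hmc_driven`` the
    fraction of them whose difference sits in the 5hmC component.
    ``confounder_species_cor`` correlates the first latent factor with the
    species label, the scenario confounder adjustment exists for.
    """

    n_probes: int = 20_000
    n_chrom: int = 4
    n_human_bs: int = 3
    n_monkey_bs: int = 7
    n_human_tab: int = 6
    n_monkey_tab: int = 11
    tab_replicates: int = 2
    state_transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.99, 0.01),
        (0.25, 0.75),
    )
    iid_states: bool = False
    effect_size: float = 2.0
    frac_hmc_driven: float = 0.5
    n_latent: int = 2
    confounder_sd: float = 0.3
    confounder_species_cor: float = 0.0
    batch_sd: float = 0.2
    noise_sd: float = 0.4
    detection_fail_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.state_transition, dtype=float)
        if A.shape != (2, 2) or not np.allclose(A.sum(axis=1), 1.0):
            raise ValueError("state_transition must be a 2x2 row-stochastic matrix")
        if np.any(A < 0):
            raise ValueError("state_transition entries must be non-negative")
        for name in ("frac_hmc_driven", "detection_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.tab_replicates < 1:
            raise ValueError("tab_replicates must be at least 1")
        if min(self.n_human_bs, self.n_monkey_bs, self.n_human_tab, self.n_monkey_tab) < 2:
            raise ValueError("need at least 2 samples per species per assay")
        if self.n_probes < self.n_chrom:
            raise ValueError("n_probes must be at least n_chrom")


@dataclass
class SimulatedDataset:
    bs_betas: pd.DataFrame
    tab_betas: pd.DataFrame
    bs_detp: pd.DataFrame
    tab_detp: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_synthetic(
    n_probes: int,
    n_chrom: int,
    seed: int = 0,
    island_frac: float = 0.30,
    intergenic_frac: float = 0.25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Probe annotation with island cassettes and realistic label marginals.

    CpG islands come in runs of 2-6 probes flanked by a north shore/shelf
    before and a south shore/shelf after (in coordinate order); everything
    else is open sea.  Region groups are drawn per gene entry with
    HM450-like weights; ``intergenic_frac`` of probes carry no gene.
    """
    if n_probes < n_chrom:
        raise ValueError("n_probes must be at least n_chrom")
    if rng is None:
        rng = np.random.default_rng(seed)

    mean_len = 4.0  # mean island run length for randint(2, 7)
    # probability of opening a cassette at a free slot, matched to island_frac
    q = island_frac / (mean_len - island_frac * (mean_len + 3.0))

    per_chrom = np.full(n_chrom, n_probes // n_chrom)
    per_chrom[: n_probes % n_chrom] += 1

    chroms: list[str] = []
    positions: list[int] = []
    islands: list[str] = []
    for c in range(n_chrom):
        n_c = int(per_chrom[c])
        labels: list[str] = []
        while len(labels) < n_c:
            if rng.random() < q:
                run = int(rng.integers(2, 7))
                labels.extend(
                    ["N_Shelf", "N_Shore"] + ["Island"] * run + ["S_Shore", "S_Shelf"]
                )
            else:
                labels.append("OpenSea")
        labels = labels[:n_c]
        gaps = rng.integers(100, 1500, size=n_c)
        pos = np.cumsum(gaps) + 1
        chroms.extend([f"chr{c + 1}"] * n_c)
        positions.extend(pos.tolist())
        islands.extend(labels)

    group_names = list(_REGION_WEIGHTS)
    group_p = np.array([_REGION_WEIGHTS[g] for g in group_names])
    group_p = group_p / group_p.sum()
    intergenic = rng.random(n_probes) < intergenic_frac
    n_genes = rng.choice([1, 2, 3], size=n_probes, p=[0.78, 0.16, 0.06])

    gene_entries = []
    for i in range(n_probes):
        if intergenic[i]:
            gene_entries.append(())
            continue
        k = int(n_genes[i])
        groups = rng.choice(group_names, size=k, p=group_p)
        genes = [f"G{int(rng.integers(0, 5000)):04d}" for _ in range(k)]
        gene_entries.append(tuple(zip(genes, groups.tolist())))

    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "gene_entries": gene_entries,
            "island_relation": islands,
            "intergenic": intergenic,
        },
        index=pd.Index([f"cg{i:07d}" for i in range(n_probes)], name="probe_id"),
    )
    return ann


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _markov_states(rng, A, n, iid):
    """0 = null, 1 = differential, started at the stationary distribution."""
    pi1 = A[0, 1] / (A[0, 1] + A[1, 0])
    if iid:
        return (rng.random(n) < pi1).astype(np.int8)
    states = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    states[0] = u[0] < pi1
    for i in range(1, n):
        p_stay = A[states[i - 1], 1]
        states[i] = u[i] < p_stay
    return states


def _baseline_logit(ann: pd.DataFrame, rng) -> np.ndarray:
    base = np.array([_ISLAND_BASE[r] for r in ann["island_relation"]])
    adj = np.array(
        [
            np.mean([_REGION_ADJUST[g] for _, g in entries]) if entries else 0.0
            for entries in ann["gene_entries"]
        ]
    )
    return base + adj + rng.normal(0.0, 0.3, size=len(ann))


def _assign_chips(sample_rows: list[dict], arm: str, chip_size: int = 8) -> None:
    """Round-robin chip assignment; replicate pairs share a chip."""
    groups = []
    seen = set()
    for r in sample_rows:
        if r["replicate_group"] not in seen:
            seen.add(r["replicate_group"])
            groups.append(r["replicate_group"])
    chip_of = {g: f"{arm}_chip{(i // chip_size) + 1}" for i, g in enumerate(groups)}
    for r in sample_rows:
        r["beadchip"] = chip_of[r["replicate_group"]]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one paired BS/TAB dataset with known per-probe truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    ann = annotate_synthetic(n, config.n_chrom, rng=rng)
    A = np.asarray(config.state_transition, dtype=float)

    # --- truth: states per chromosome, driver, signed logit effect
    states = np.concatenate(
        [
            _markov_states(rng, A, (ann["chrom"] == c).sum(), config.iid_states)
            for c in pd.unique(ann["chrom"])
        ]
    )
    if config.effect_size == 0:
        states = np.zeros(n, dtype=np.int8)
    diff = states == 1
    driver = np.array(["none"] * n, dtype=object)
    hmc_driven = rng.random(n) < config.frac_hmc_driven
    driver[diff & hmc_driven] = "5hmC"
    driver[diff & ~hmc_driven] = "5mC"
    sign = rng.choice([-1.0, 1.0], size=n)
    magnitude = rng.gamma(shape=4.0, scale=config.effect_size / 4.0, size=n)
    shift = np.where(diff, sign * magnitude, 0.0)

    # --- per-probe component levels
    total = np.clip(_expit(_baseline_logit(ann, rng)), _EPS, 1 - _EPS)
    rho = rng.uniform(0.1, 0.5, size=n)  # hydroxymethyl fraction of composite
    m_hmc = np.clip(rho * total, _EPS, 1 - _EPS)
    m_mc = np.clip((1.0 - rho) * total, _EPS, 1 - _EPS)

    def species_components(sp_sign: float):
        """Expected (5mC, 5hmC) per probe for one species; sp_sign = +-1."""
        half = 0.5 * sp_sign * shift
        mc = m_mc.copy()
        hmc = m_hmc.copy()
        is_mc = driver == "5mC"
        is_hmc = driver == "5hmC"
        mc[is_mc] = _expit(_logit(m_mc[is_mc]) + half[is_mc])
        hmc[is_hmc] = _expit(_logit(m_hmc[is_hmc]) + half[is_hmc])
        return mc, hmc

    mc_h, hmc_h = species_components(+1.0)
    mc_m, hmc_m = species_components(-1.0)
    bs_h = np.clip(mc_h + hmc_h, _EPS, 1 - _EPS)
    bs_m = np.clip(mc_m + hmc_m, _EPS, 1 - _EPS)

    delta_assay = np.where(driver == "5hmC", hmc_h - hmc_m, bs_h - bs_m)
    truth = pd.DataFrame(
        {
            "true_state": np.where(diff, "differential", "null"),
            "driver": driver,
            "true_delta_beta": np.where(diff, delta_assay, 0.0),
        },
        index=ann.index,
    )

    # --- sample sheet
    rows: list[dict] = []
    bs_rows: list[dict] = []
    for sp, count in (("human", config.n_human_bs), ("monkey", config.n_monkey_bs)):
        for i in range(count):
            sid = f"{sp[0]}_bs_{i + 1}"
            bs_rows.append(
                {"sample_id": sid, "species": sp, "assay": "BS", "replicate_group": sid}
            )
    _assign_chips(bs_rows, "BS")
    tab_rows: list[dict] = []
    for sp, count in (("human", config.n_human_tab), ("monkey", config.n_monkey_tab)):
        for i in range(count):
            base = f"{sp[0]}_tab_{i + 1}"
            for r in range(config.tab_replicates):
                tab_rows.append(
                    {
                        "sample_id": f"{base}{chr(ord('a') + r)}",
                        "species": sp,
                        "assay": "TAB",
                        "replicate_group": base,
                    }
                )
    _assign_chips(tab_rows, "TAB")
    rows = bs_rows + tab_rows
    sheet = validate_sample_sheet(pd.DataFrame(rows)[
        ["sample_id", "species", "assay", "beadchip", "replicate_group"]
    ])

    # --- latent confounders: probe loadings shared across arms,
    #     scores per biological sample (shared by technical replicates)
    k = config.n_latent
    lam = rng.normal(0.0, config.confounder_sd, size=(n, k)) if k else np.zeros((n, 0))

    def biological_groups(arm_rows):
        out, seen = [], set()
        for r in arm_rows:
            g = r["replicate_group"]
            if g not in seen:
                seen.add(g)
                out.append((g, r["species"]))
        return out

    def factor_scores(groups):
        scores = {}
        cor = config.confounder_species_cor
        for g, sp in groups:
            f = rng.normal(0.0, 1.0, size=k)
            if k and cor:
                s = 1.0 if sp == "human" else -1.0
                f[0] = cor * s + np.sqrt(1.0 - cor**2) * f[0]
            scores[g] = f
        return scores

    def chip_offsets(arm_rows):
        chips = sorted({r["beadchip"] for r in arm_rows})
        return {c: rng.normal(0.0, config.batch_sd, size=n) for c in chips}

    def build_matrix(arm_rows, expected_h, expected_m, scores, chips):
        cols = {}
        for r in arm_rows:
            mu = expected_h if r["species"] == "human" else expected_m
            eta = _logit(np.clip(mu, _EPS, 1 - _EPS))
            eta = eta + lam @ scores[r["replicate_group"]] + chips[r["beadchip"]]
            eta = eta + rng.normal(0.0, config.noise_sd, size=n)
            cols[r["sample_id"]] = _expit(eta)
        return pd.DataFrame(cols, index=ann.index)

    bs_scores = factor_scores(biological_groups(bs_rows))
    tab_scores = factor_scores(biological_groups(tab_rows))
    bs_betas = build_matrix(bs_rows, bs_h, bs_m, bs_scores, chip_offsets(bs_rows))
    tab_betas = build_matrix(tab_rows, hmc_h, hmc_m, tab_scores, chip_offsets(tab_rows))

    def detection_p(shape):
        p = rng.uniform(0.0, 0.009, size=shape)
        fail = rng.random(shape) < config.detection_fail_rate
        p[fail] = rng.uniform(0.011, 1.0, size=int(fail.sum()))
        return p

    bs_detp = pd.DataFrame(
        detection_p(bs_betas.shape), index=bs_betas.index, columns=bs_betas.columns
    )
    tab_detp = pd.DataFrame(
        detection_p(tab_betas.shape), index=tab_betas.index, columns=tab_betas.columns
    )

    return SimulatedDataset(
        bs_betas=bs_betas,
        tab_betas=tab_betas,
        bs_detp=bs_detp,
        tab_detp=tab_detp,
        sheet=sheet,
        annotation=ann,
        truth=truth,
        config=config,
    )


def simulate_z_chain(
    n: int,
    A=((0.95, 0.05), (0.20, 0.80)),
    alt_mean: float = 3.0,
    alt_sd: float = 1.0,
    null_mean: float = 0.0,
    null_sd: float = 1.0,
    seed: int = 0,
    symmetric_alt: bool = False,
):
    """Genome-ordered z-scores from a known two-state HMM.

    Returns ``(z, states)`` with states 0 = null, 1 = non-null.  Used for
    FDR-calibration and parameter-recovery experiments where the chain is
    the object of interest rather than the full array pipeline.
    """
    rng = np.random.default_rng(seed)
    A = np.asarray(A, dtype=float)
    states = _markov_states(rng, A, n, iid=False)
    z = rng.normal(null_mean, null_sd, size=n)
    alt = states == 1
    mean = np.full(n, alt_mean)
    if symmetric_alt:
        mean *= rng.choice([-1.0, 1.0], size=n)
    z[alt] = rng.normal(mean[alt], alt_sd)
    return z, states
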