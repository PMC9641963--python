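"""Trio-based de novo germline mutation-rate estimation.

The pipeline consumes two base-pair-resolution trio genotype tables, one per
mapping target (the maternal and paternal haplotype assemblies), and applies:

1. site-level caller-annotation filters (QD, FS, MQ, rank sums, SOR);
2. per-individual depth / genotype-quality filters, plus candidate screening
   on parental alternate-allele reads and offspring allelic balance;
3. the dual-configuration candidate intersection — a true de novo mutation
   appears as homozygous-reference parents with a heterozygous offspring on
   the mapping lacking the mutant allele, and homozygous-alternative parents
   with a heterozygous offspring on the mapping carrying it, with read
   support shared across the two call sets (an evidence token here);
4. callability (sites with full detection power: DP, GQ and parental AD
   filters pass) and a false-negative-rate correction for losses a true
   variant would have suffered from the allelic-balance and site filters;
5. rate = candidates / FNR-corrected diploid callable sites.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDIVIDUALS = ("offspring", "father", "mother")
PARENTS = ("father", "mother")
SITE_ANNOTATIONS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


@dataclass
class FilterConfig:
    qd_min: float = 2.0
    fs_max: float = 20.0
    mq_min: float = 40.0
    mq_rank_low: float = -2.0
    mq_rank_high: float = 4.0
    read_pos_rank_low: float = -3.0
    read_pos_rank_high: float = 3.0
    sor_max: float = 3.0
    dp_window: tuple[float, float] = (0.5, 2.0)
    mean_depths: dict[str, float] = field(
        default_factory=lambda: {"offspring": 56.0, "father": 78.0, "mother": 84.0}
    )
    gq_min: float = 60.0
    ab_window: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self):
        if not (self.dp_window[0] < self.dp_window[1]):
            raise ValueError("dp_window must be ordered")
        if not (0 <= self.ab_window[0] < self.ab_window[1] <= 1):
            raise ValueError("ab_window must be ordered within [0, 1]")


@dataclass
class MutationRateEstimate:
    n_maternal: int
    n_paternal: int
    callability_maternal: float
    callability_paternal: float
    fnr: float
    diploid_callable: float
    rate: float


def _site_fail_masks(df: pd.DataFrame, cfg: FilterConfig) -> dict[str, pd.Series]:
    """Per-threshold failure masks; missing annotations pass (permissive)."""
    missing = [c for c in SITE_ANNOTATIONS if df[c].isna().any()]
    if missing:
        logger.info("missing site annotations treated as passing: %s", missing)
    return {
        "QD": df["QD"] < cfg.qd_min,
        "FS": df["FS"] > cfg.fs_max,
        "MQ": df["MQ"] < cfg.mq_min,
        "MQRankSum_low": df["MQRankSum"] < cfg.mq_rank_low,
        "MQRankSum_high": df["MQRankSum"] > cfg.mq_rank_high,
        "ReadPosRankSum_low": df["ReadPosRankSum"] < cfg.read_pos_rank_low,
        "ReadPosRankSum_high": df["ReadPosRankSum"] > cfg.read_pos_rank_high,
        "SOR": df["SOR"] > cfg.sor_max,
    }


def site_filter(site: pd.Series | dict, cfg: FilterConfig | None = None) -> tuple[bool, list[str]]:
    """Pass/fail plus the reason codes of every violated site-level threshold."""
    cfg = cfg or FilterConfig()
    df = pd.DataFrame([dict(site)])
    masks = _site_fail_masks(df, cfg)
    reasons = [name for name, mask in masks.items() if bool(mask.iloc[0])]
    return (not reasons), reasons


def site_filter_table(df: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.Series:
    """Vectorized site-level pass mask."""
    cfg = cfg or FilterConfig()
    fail = pd.Series(False, index=df.index)
    for mask in _site_fail_masks(df, cfg).values():
        fail |= mask.fillna(False)
    return ~fail


def allelic_balance(df: pd.DataFrame, individual: str) -> pd.Series:
    dp = df[f"DP_{individual}"].astype(float)
    return (df[f"AD_{individual}"] / dp.where(dp > 0)).fillna(0.0)


def individual_filter(
    site: pd.Series | dict, cfg: FilterConfig | None = None
) -> dict[str, tuple[bool, list[str]]]:
    """Per-individual pass/fail with reasons.

    DP must lie within the per-individual window around the configured mean
    and GQ must reach the minimum. For candidate screening, a parent fails on
    any alternate-allele read (AD > 0) and the offspring fails on an allelic
    balance outside the configured window.
    """
    cfg = cfg or FilterConfig()
    df = pd.DataFrame([dict(site)])
    out = {}
    for ind in INDIVIDUALS:
        reasons = []
        if not bool(dp_gq_pass(df, ind, cfg).iloc[0]):
            dp = float(df[f"DP_{ind}"].iloc[0])
            mean = cfg.mean_depths[ind]
            if not (cfg.dp_window[0] * mean <= dp <= cfg.dp_window[1] * mean):
                reasons.append("DP")
            if float(df[f"GQ_{ind}"].iloc[0]) < cfg.gq_min:
                reasons.append("GQ")
        if ind in PARENTS and int(df[f"AD_{ind}"].iloc[0]) > 0:
            reasons.append("AD")
        if ind == "offspring":
            ab = float(allelic_balance(df, ind).iloc[0])
            gt = str(df[f"GT_{ind}"].iloc[0])
            if gt == "0/1" and not (cfg.ab_window[0] <= ab <= cfg.ab_window[1]):
                reasons.append("AB")
        out[ind] = (not reasons, reasons)
    return out


def dp_gq_pass(df: pd.DataFrame, individual: str, cfg: FilterConfig) -> pd.Series:
    mean = cfg.mean_depths[individual]
    dp = df[f"DP_{individual}"].astype(float)
    gq = df[f"GQ_{individual}"].astype(float)
    return (
        (dp >= cfg.dp_window[0] * mean)
        & (dp <= cfg.dp_window[1] * mean)
        & (gq >= cfg.gq_min)
    )


def _all_dp_gq_pass(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    for ind in INDIVIDUALS:
        mask &= dp_gq_pass(df, ind, cfg)
    return mask


def _config_mask(df: pd.DataFrame, parent_gt: str, cfg: FilterConfig) -> pd.Series:
    """Candidate genotype configuration plus all individual-level screening."""
    mask = (
        (df["GT_father"] == parent_gt)
        & (df["GT_mother"] == parent_gt)
        & (df["GT_offspring"] == "0/1")
        & _all_dp_gq_pass(df, cfg)
    )
    ab = allelic_balance(df, "offspring")
    mask &= (ab >= cfg.ab_window[0]) & (ab <= cfg.ab_window[1])
    if parent_gt == "0/0":
        for parent in PARENTS:
            mask &= df[f"AD_{parent}"] == 0
    return mask


def find_candidates(
    table_maternal_mapping: pd.DataFrame,
    table_paternal_mapping: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """De novo candidates by origin, via the dual-mapping intersection.

    Maternal candidates are heterozygous in the offspring with 0/0 parents on
    the paternal mapping and 1/1 parents on the maternal mapping; paternal
    candidates are the mirror image. Both rows must pass the site and
    individual filters and share an evidence token (read-name overlap).
    """
    cfg = cfg or FilterConfig()
    tm, tp = table_maternal_mapping, table_paternal_mapping
    if not (set(tm["CHROM"]) & set(tp["CHROM"])):
        raise ValueError("mapping tables share no scaffold names; cannot intersect")

    key = ["CHROM", "POS"]
    merged = tm.merge(tp, on=key, suffixes=("_mat", "_pat"))

    def split(side: str) -> pd.DataFrame:
        cols = {c: c[: -len(f"_{side}")] for c in merged.columns if c.endswith(f"_{side}")}
        df = merged[key + list(cols)].rename(columns=cols)
        return df

    mat_side = split("mat")
    pat_side = split("pat")
    site_ok = site_filter_table(mat_side, cfg) & site_filter_table(pat_side, cfg)
    token_ok = (
        (mat_side["EV_offspring"] >= 0)
        & (mat_side["EV_offspring"] == pat_side["EV_offspring"])
    )

    maternal = (
        _config_mask(pat_side, "0/0", cfg)
        & _config_mask(mat_side, "1/1", cfg)
        & site_ok & token_ok
    )
    paternal = (
        _config_mask(mat_side, "0/0", cfg)
        & _config_mask(pat_side, "1/1", cfg)
        & site_ok & token_ok
    )
    to_sites = lambda mask: list(
        merged.loc[mask, key].itertuples(index=False, name=None)
    )
    return to_sites(maternal), to_sites(paternal)


def callability(table: pd.DataFrame, cfg: FilterConfig | None = None) -> int:
    """Sites with full detection power: DP and GQ pass for all three
    individuals and both parents carry zero alternate-allele reads.

    Site-level and allelic-balance filters are deliberately not applied here;
    their effect on true variants is captured by the FNR correction.
    """
    cfg = cfg or FilterConfig()
    mask = _all_dp_gq_pass(table, cfg)
    for parent in PARENTS:
        mask &= table[f"AD_{parent}"] == 0
    return int(mask.sum())


def estimate_fnr(table: pd.DataFrame, cfg: FilterConfig | None = None) -> float:
    """False-negative rate from obligate-heterozygous transmission sites.

    At sites where one parent is 0/0 and the other 1/1, the offspring must be
    heterozygous; the fraction of such sites removed by the allelic-balance
    filter, combined multiplicatively with the fraction a variant would lose
    to the site-level filters, gives the FNR applied to callability.
    """
    cfg = cfg or FilterConfig()
    obligate = table[
        (
            ((table["GT_father"] == "0/0") & (table["GT_mother"] == "1/1"))
            | ((table["GT_father"] == "1/1") & (table["GT_mother"] == "0/0"))
        )
        & (table["GT_offspring"] == "0/1")
    ]
    if len(obligate) == 0:
        raise ValueError("no obligate-heterozygous sites; FNR undefined")
    ab = allelic_balance(obligate, "offspring")
    ab_survive = float(
        ((ab >= cfg.ab_window[0]) & (ab <= cfg.ab_window[1])).mean()
    )
    site_survive = float(site_filter_table(obligate, cfg).mean())
    return 1.0 - ab_survive * site_survive


def mutation_rate(
    n_maternal: int,
    n_paternal: int,
    callability_maternal: float,
    callability_paternal: float,
    fnr: float,
) -> MutationRateEstimate:
    """Per-site, per-generation de novo mutation rate.

    The diploid callable size is the summed per-assembly callability scaled
    by (1 − FNR); the rate is the total candidate count over that size.
    """
    if callability_maternal <= 0 or callability_paternal <= 0:
        raise ValueError("callabilities must be > 0")
    if not (0.0 <= fnr < 1.0):
        raise ValueError("fnr must lie in [0, 1)")
    diploid = (callability_maternal + callability_paternal) * (1.0 - fnr)
    rate = (n_maternal + n_paternal) / diploid
    return MutationRateEstimate(
        n_maternal=n_maternal,
        n_paternal=n_paternal,
        callability_maternal=callability_maternal,
        callability_paternal=callability_paternal,
        fnr=fnr,
        diploid_callable=diploid,
        rate=rate,
    )


def summarize(estimate: MutationRateEstimate) -> str:
    """Human-readable report of a mutation-rate estimate."""
    return (
        f"de novo candidates: {estimate.n_maternal} maternal + "
        f"{estimate.n_paternal} paternal\n"
        f"callability: maternal {estimate.callability_maternal:,.0f} bp, "
        f"paternal {estimate.callability_paternal:,.0f} bp\n"
        f"FNR: {estimate.fnr:.3f}\n"
        f"diploid callable: {estimate.diploid_callable:,.0f} bp\n"
        f"rate: {estimate.rate:.3e} per site per generation "
        f"({estimate.rate * 1e8:.2f} x 1e-8)"
    )
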