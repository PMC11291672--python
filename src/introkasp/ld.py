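"""Linkage disequilibrium from unphased genotypes via EM.

For a pair of biallelic loci, unphased diploid genotypes determine the
four two-locus haplotype counts exactly except for double heterozygotes,
which are an equal-evidence mixture of the two phase resolutions
(AB/ab vs Ab/aB).  The classic EM iteration resolves this: the E-step
splits double heterozygotes in the ratio p_AB·p_ab : p_Ab·p_aB under the
current haplotype frequencies, and the M-step re-normalises the expected
gamete counts.  From the converged frequencies, D = p_AB − p_A·p_B and
r² = D² / (p_A(1−p_A) p_B(1−p_B)).

Per-population, per-period r² matrices over the island markers feed the
temporal comparison: mean r² per pair across retained populations in each
period, the per-pair delta, and — because the island pairs are not
independent — separate sign tests and one-sided Wilcoxon tests within the
core–shoulder, within-left and within-right pair classes.  Populations
are retained per period only if the robusta-allele frequency at the core
SNP exceeds a threshold (default 0.05): below that, diversity is too low
for r² to be informative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .panel import PairClass, Panel
from .popstats import TestResult, sign_test, wilcoxon_signed_rank_one_sided

logger = logging.getLogger("introkasp")

__all__ = [
    "LdEstimate",
    "two_locus_counts",
    "em_haplotype_freqs",
    "ld_from_dosages",
    "ld_matrices",
    "ld_temporal_compare",
    "mean_r2",
]


@dataclass
class LdEstimate:
    """EM-estimated two-locus haplotype frequencies and LD summaries.

    ``hap_freqs`` orders the four haplotypes (AB, Ab, aB, ab) with A/B the
    robusta alleles at the two loci.  ``r2`` is NaN when either locus is
    monomorphic in the sample.
    """

    hap_freqs: np.ndarray
    D: float
    r2: float
    n: int
    converged: bool
    loglik: float
    n_iter: int

    @property
    def p_A(self) -> float:
        return float(self.hap_freqs[0] + self.hap_freqs[1])

    @property
    def p_B(self) -> float:
        return float(self.hap_freqs[0] + self.hap_freqs[2])


def two_locus_counts(dos_a, dos_b) -> np.ndarray:
    """3×3 joint dosage table; individuals missing either locus excluded."""
    dos_a = np.asarray(dos_a, dtype=float)
    dos_b = np.asarray(dos_b, dtype=float)
    ok = ~(np.isnan(dos_a) | np.isnan(dos_b))
    counts = np.zeros((3, 3), dtype=int)
    for i, j in zip(dos_a[ok].astype(int), dos_b[ok].astype(int)):
        counts[i, j] += 1
    return counts


def _genotype_log_likelihood(counts: np.ndarray, p: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3×3 dosage table under HWE.

    Genotype probabilities are products of haplotype frequencies; the
    double-heterozygote class sums both phase resolutions.
    """
    pAB, pAb, paB, pab = p
    g = np.empty((3, 3))
    g[2, 2] = pAB**2
    g[2, 1] = 2 * pAB * pAb
    g[2, 0] = pAb**2
    g[1, 2] = 2 * pAB * paB
    g[1, 1] = 2 * (pAB * pab + pAb * paB)
    g[1, 0] = 2 * pAb * pab
    g[0, 2] = paB**2
    g[0, 1] = 2 * paB * pab
    g[0, 0] = pab**2
    with np.errstate(divide="ignore"):
        logg = np.log(g)
    mask = counts > 0
    if np.any(np.isneginf(logg[mask])):
        return -np.inf
    return float((counts[mask] * logg[mask]).sum())


def em_haplotype_freqs(
    counts: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    check_monotone: bool = False,
) -> LdEstimate:
    """EM estimate of two-locus haplotype frequencies from a dosage table.

    Starts at linkage equilibrium (p_AB⁰ = p_A·p_B) and iterates until the
    largest haplotype-frequency change falls below ``tol``.  With no
    double heterozygotes the first M-step already equals direct gamete
    counting and the estimate is exact.  ``check_monotone`` asserts the
    observed-data log-likelihood never decreases (debug aid).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError(f"expected a 3x3 dosage table, got {counts.shape}")
    n = counts.sum()
    if n == 0:
        raise ValueError("no individuals called at both loci")
    dosA = np.arange(3)[:, None]
    dosB = np.arange(3)[None, :]
    p_A = float((counts * dosA).sum() / (2 * n))
    p_B = float((counts * dosB).sum() / (2 * n))
    # known gamete counts (everything but the double heterozygotes)
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1]
    base[3] = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1]
    n_dh = counts[1, 1]
    p = np.array(
        [p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)]
    )
    loglik = _genotype_log_likelihood(counts, p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num_cis = p[0] * p[3]
        num_trans = p[1] * p[2]
        denom = num_cis + num_trans
        w = 0.5 if denom == 0 else num_cis / denom  # 50/50 at the saddle
        hap = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        p_new = hap / (2 * n)
        if check_monotone:
            ll_new = _genotype_log_likelihood(counts, p_new)
            assert ll_new >= loglik - 1e-9, "EM log-likelihood decreased"
            loglik = ll_new
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            converged = True
            break
    loglik = _genotype_log_likelihood(counts, p)
    pA, pB = p[0] + p[1], p[0] + p[2]
    D = float(p[0] - pA * pB)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = float(D * D / denom) if denom > 0 else np.nan
    return LdEstimate(
        hap_freqs=p, D=D, r2=r2, n=int(n), converged=converged,
        loglik=loglik, n_iter=it,
    )


def ld_from_dosages(dos_a, dos_b, **kwargs) -> LdEstimate:
    """Convenience: EM LD estimate straight from two dosage vectors."""
    return em_haplotype_freqs(two_locus_counts(dos_a, dos_b), **kwargs)


# ---------------------------------------------------------------------------
# per-population matrices and temporal comparison


def ld_matrices(
    matrix: GenotypeMatrix,
    panel: Panel,
    min_core_freq: float = 0.05,
    min_n: int = 5,
) -> pd.DataFrame:
    """Pairwise island r² per (population, period), long format.

    A (population, period) stratum is retained only if the robusta-allele
    frequency at the core SNP in that stratum exceeds ``min_core_freq``
    (retention is decided per period).  Returns columns population_id,
    period, marker_a, marker_b, pair_class, r2, D, n, converged plus a
    per-stratum ``included`` flag on every row (excluded strata appear
    with included=False and no r² rows).
    """
    core = panel.core_marker_id
    island = [m for m in panel.island_marker_ids if m in matrix.dosage.columns]
    rows = []
    meta = matrix.meta
    groups = meta.groupby(["population_id", "period"], sort=True)
    any_included = False
    for (pop, period), grp in groups:
        dos = matrix.dosage.loc[grp.index]
        core_called = dos[core].dropna()
        freq = core_called.sum() / (2 * len(core_called)) if len(core_called) else np.nan
        included = bool(freq > min_core_freq) if not np.isnan(freq) else False
        if not included:
            rows.append(
                {
                    "population_id": pop, "period": period, "marker_a": None,
                    "marker_b": None, "pair_class": None, "r2": np.nan,
                    "D": np.nan, "n": 0, "converged": False,
                    "core_freq": freq, "included": False,
                }
            )
            continue
        any_included = True
        for a, b in itertools.combinations(island, 2):
            counts = two_locus_counts(dos[a], dos[b])
            if counts.sum() < min_n:
                continue
            est = em_haplotype_freqs(counts)
            rows.append(
                {
                    "population_id": pop, "period": period, "marker_a": a,
                    "marker_b": b, "pair_class": panel.pair_class(a, b).value,
                    "r2": est.r2, "D": est.D, "n": est.n,
                    "converged": est.converged, "core_freq": freq,
                    "included": True,
                }
            )
    if not any_included:
        logger.warning("no population passed the core-frequency filter %.3f", min_core_freq)
    return pd.DataFrame(rows)


def mean_r2(
    ld_long: pd.DataFrame,
    period: str,
    aggregation: str = "population_pair",
) -> float:
    """Mean r² for one period over retained populations.

    ``population_pair`` (primary): unweighted mean over every defined
    (population, pair) value.  ``pair_then_population``: average within
    pair across populations first, then across pairs.  ``population_then_pair``:
    average within population first.
    """
    sub = ld_long[(ld_long["period"] == period) & ld_long["included"]].dropna(
        subset=["r2"]
    )
    if sub.empty:
        return np.nan
    if aggregation == "population_pair":
        return float(sub["r2"].mean())
    if aggregation == "pair_then_population":
        return float(sub.groupby(["marker_a", "marker_b"])["r2"].mean().mean())
    if aggregation == "population_then_pair":
        return float(sub.groupby("population_id")["r2"].mean().mean())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def ld_temporal_compare(
    ld_long: pd.DataFrame,
    panel: Panel,
    periods: tuple[str, str] = ("P2012", "P2021"),
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Per-pair temporal r² deltas and per-class decrease tests.

    For each island pair, r² is averaged across retained populations
    within each period; ``delta`` is period-2 minus period-1.  Pairs
    missing in one period are excluded from their class with a log entry.
    Within each pair class (core–shoulder, within-left, within-right) a
    two-sided exact sign test and a one-sided Wilcoxon signed-rank test
    (alternative: decrease) summarise the direction of change; an overall
    decrease count over all pairs and per-population decrease/increase
    counts per pair are also reported.
    """
    pa, pb = periods
    sub = ld_long[ld_long["included"]].dropna(subset=["r2"])
    per_pair = (
        sub.groupby(["marker_a", "marker_b", "pair_class", "period"])["r2"]
        .mean()
        .unstack("period")
    )
    rows = []
    for (a, b, cls), rec in per_pair.iterrows():
        r2_a = rec.get(pa, np.nan)
        r2_b = rec.get(pb, np.nan)
        if np.isnan(r2_a) or np.isnan(r2_b):
            logger.info("pair %s-%s missing in one period; excluded", a, b)
            continue
        # per-population direction counts (Fig-style cell annotations)
        wide = (
            sub[(sub["marker_a"] == a) & (sub["marker_b"] == b)]
            .pivot_table(index="population_id", columns="period", values="r2")
        )
        both = wide.dropna(subset=[p for p in periods if p in wide.columns], how="any") \
            if set(periods) <= set(wide.columns) else wide.iloc[0:0]
        n_pop_dec = int((both[pb] < both[pa]).sum()) if len(both) else 0
        n_pop_inc = int((both[pb] > both[pa]).sum()) if len(both) else 0
        rows.append(
            {
                "marker_a": a, "marker_b": b, "pair_class": cls,
                f"r2_{pa}": float(r2_a), f"r2_{pb}": float(r2_b),
                "delta": float(r2_b - r2_a),
                "n_populations_decrease": n_pop_dec,
                "n_populations_increase": n_pop_inc,
            }
        )
    delta_columns = [
        "marker_a", "marker_b", "pair_class", f"r2_{pa}", f"r2_{pb}",
        "delta", "n_populations_decrease", "n_populations_increase",
    ]
    delta = pd.DataFrame(rows, columns=delta_columns)
    tests: list[TestResult] = []
    if delta.empty:
        return delta, tests
    for cls in (
        PairClass.CORE_SHOULDER.value,
        PairClass.LEFT_SHOULDER.value,
        PairClass.RIGHT_SHOULDER.value,
    ):
        cls_delta = delta[delta["pair_class"] == cls]
        if cls_delta.empty:
            continue
        n = len(cls_delta)
        k = int((cls_delta["delta"] < 0).sum())
        st = sign_test(k, n, sidedness="two_sided", label=f"{cls}:sign")
        st.extras["n_decreases"] = k
        tests.append(st)
        tests.append(
            wilcoxon_signed_rank_one_sided(
                cls_delta[f"r2_{pa}"], cls_delta[f"r2_{pb}"],
                alternative="less", label=f"{cls}:wilcoxon",
            )
        )
    k_all = int((delta["delta"] < 0).sum())
    overall = sign_test(k_all, len(delta), sidedness="two_sided", label="all_pairs:sign")
    overall.extras["n_decreases"] = k_all
    tests.append(overall)
    return delta, tests
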