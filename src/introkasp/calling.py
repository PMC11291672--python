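"""KASP genotype calling from two-channel fluorescence.

The variant allele fluorescent fraction (VAFF) of a well is
``f1 / (f1 + f2)`` with ``f1`` the robusta-specific channel: near 1 for
robusta homozygotes, near 0 for intestinalis homozygotes, intermediate for
heterozygotes.  Each run carries four positive-control wells (one
*C. robusta*, one non-introgressed *C. intestinalis*, two introgressed
*C. intestinalis*); cutoffs separating the three clusters are calibrated
per run and assay from those controls, automating the manual
control-anchored geometry used at the bench.  Calls within a configurable
margin of a cutoff are flagged ``near_cutoff`` and excluded from frequency
computations by default.

The pooled 11-SNP multiplex reaction yields a VAFF that estimates the
genome-wide hybrid index; thresholds on it assign individuals to pure
*C. robusta*, pure *C. intestinalis* or admixed categories, cross-checked
against the mitochondrial assay for concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MULTIPLEX_ASSAY, GenotypeMatrix
from .panel import Panel, Region

logger = logging.getLogger("introkasp")

__all__ = [
    "compute_vaff",
    "CutoffSet",
    "calibrate_cutoffs",
    "call_genotype",
    "call_plate",
    "compute_hybrid_index",
    "classify_individual",
    "build_genotype_matrix",
    "DEFAULT_CUTOFFS",
    "DEFAULT_MARGIN",
    "HYBRID_THRESHOLDS",
]

#: fallback cutoffs when a run has no usable homozygote controls
DEFAULT_CUTOFFS = (0.33, 0.66)

#: VAFF distance to a cutoff below which a call is flagged near_cutoff
DEFAULT_MARGIN = 0.05

#: hybrid-index category thresholds (t_low, t_high): chosen so that an
#: individual heterozygous at >=3 of the 11 multiplex loci (pooled VAFF
#: >= 3/22 under balanced channels) is classified admixed, which keeps
#: first- and second-generation backcrosses detectable.
HYBRID_THRESHOLDS = (0.125, 0.875)


def compute_vaff(f1, f2):
    """Variant allele fluorescent fraction ``f1 / (f1 + f2)``.

    Accepts scalars or arrays; wells with zero total signal give NaN
    (a failed record, not an exception).  Scale-invariant by construction.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    total = f1 + f2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, f1 / np.where(total > 0, total, 1.0), np.nan)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class CutoffSet:
    """Per-run, per-assay VAFF cutoffs separating the three clusters."""

    run_id: str
    assay_id: str
    lower: float
    upper: float
    margin: float = DEFAULT_MARGIN
    from_controls: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ValueError(
                f"invalid cutoffs for {self.run_id}/{self.assay_id}: "
                f"need 0 < lower < upper < 1, got ({self.lower}, {self.upper})"
            )
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def calibrate_cutoffs(
    controls: pd.DataFrame,
    run_id: str,
    assay_id: str,
    defaults: tuple[float, float] = DEFAULT_CUTOFFS,
    margin: float = DEFAULT_MARGIN,
) -> CutoffSet:
    """Derive cluster cutoffs from one run's positive-control wells.

    The lower cutoff is the midpoint between the intestinalis-homozygote
    and heterozygote cluster means, the upper between heterozygote and
    robusta-homozygote.  The heterozygote cluster is anchored by
    introgressed-intestinalis controls whose VAFF falls between the two
    homozygote clusters (i.e. the control is heterozygous at this assay);
    otherwise it is synthesized at the homozygote-mean midpoint.  With
    either homozygote control missing, the configured default cutoffs are
    used and a warning logged.
    """
    ctl = controls[(controls["run_id"] == run_id) & (controls["assay_id"] == assay_id)]
    failed = (
        ctl["failed"] if "failed" in ctl.columns else (ctl["f1"] + ctl["f2"]) == 0
    )
    ctl = ctl[ctl["is_control"] & ~failed]
    vaff = compute_vaff(ctl["f1"].to_numpy(), ctl["f2"].to_numpy())
    vaff = pd.Series(np.atleast_1d(vaff), index=ctl.index)
    by_class = {
        cls: vaff[ctl["control_class"] == cls].dropna()
        for cls in ("robusta", "intestinalis_plain", "intestinalis_introgressed")
    }
    if by_class["robusta"].empty or by_class["intestinalis_plain"].empty:
        logger.warning(
            "run %s assay %s: missing homozygote control(s); using default cutoffs %s",
            run_id, assay_id, defaults,
        )
        return CutoffSet(run_id, assay_id, defaults[0], defaults[1], margin,
                         from_controls=False)
    mean_rob = float(by_class["robusta"].mean())
    mean_int = float(by_class["intestinalis_plain"].mean())
    lo_homo, hi_homo = sorted((mean_int, mean_rob))
    span = hi_homo - lo_homo
    # introgressed controls anchor the het cluster only where they actually
    # sit between the homozygote clusters (they are homozygous native at
    # assays outside their introgressed tract)
    het_candidates = by_class["intestinalis_introgressed"]
    het_candidates = het_candidates[
        (het_candidates > lo_homo + 0.2 * span) & (het_candidates < hi_homo - 0.2 * span)
    ]
    if het_candidates.empty:
        mean_het = 0.5 * (mean_int + mean_rob)
    else:
        mean_het = float(het_candidates.mean())
    lower = 0.5 * (mean_int + mean_het)
    upper = 0.5 * (mean_het + mean_rob)
    return CutoffSet(run_id, assay_id, lower, upper, margin)


def call_genotype(vaff: float, cutoffs: CutoffSet) -> tuple[float, str]:
    """Call robusta-allele dosage from a VAFF value.

    Returns ``(dosage, flag)`` with dosage in {0, 1, 2, NaN} and flag in
    {"clear", "near_cutoff", "failed"}.  Dosage is 0 below the lower
    cutoff, 2 above the upper, 1 between (cutoff values inclusive in the
    heterozygote band); a call within ``margin`` of either cutoff is
    flagged near_cutoff.
    """
    if vaff is None or np.isnan(vaff):
        return np.nan, "failed"
    if vaff < cutoffs.lower:
        dosage = 0.0
    elif vaff > cutoffs.upper:
        dosage = 2.0
    else:
        dosage = 1.0
    near = min(abs(vaff - cutoffs.lower), abs(vaff - cutoffs.upper)) < cutoffs.margin
    return dosage, ("near_cutoff" if near else "clear")


def call_plate(
    fluor: pd.DataFrame,
    panel: Panel,
    defaults: tuple[float, float] = DEFAULT_CUTOFFS,
    margin: float = DEFAULT_MARGIN,
    cutoff_overrides: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Call genotypes for every non-control simplex record of a plate table.

    Cutoffs are calibrated per (run, assay) from that run's control wells;
    ``cutoff_overrides`` maps (run_id, assay_id) to hand-curated (lower,
    upper) pairs and takes precedence, so manual curation can be
    reproduced.  Returns a long table: individual_id, population_id,
    period, run_id, marker_id, vaff, dosage, flag, plus the cutoffs used.
    """
    fluor = fluor.copy()
    if "failed" not in fluor.columns:
        fluor["failed"] = (fluor["f1"] + fluor["f2"]) == 0
    controls = fluor[fluor["is_control"]]
    samples = fluor[~fluor["is_control"] & (fluor["assay_id"] != MULTIPLEX_ASSAY)]
    rows = []
    for (run_id, assay_id), grp in samples.groupby(["run_id", "assay_id"], sort=True):
        if cutoff_overrides and (run_id, assay_id) in cutoff_overrides:
            lo, hi = cutoff_overrides[(run_id, assay_id)]
            cuts = CutoffSet(run_id, assay_id, lo, hi, margin, from_controls=False)
        else:
            cuts = calibrate_cutoffs(controls, run_id, assay_id, defaults, margin)
        vaff = np.atleast_1d(compute_vaff(grp["f1"].to_numpy(), grp["f2"].to_numpy()))
        dosage = np.select(
            [np.isnan(vaff), vaff < cuts.lower, vaff > cuts.upper],
            [np.nan, 0.0, 2.0],
            default=1.0,
        )
        near = (
            np.minimum(np.abs(vaff - cuts.lower), np.abs(vaff - cuts.upper))
            < cuts.margin
        )
        flag = np.where(np.isnan(vaff), "failed", np.where(near, "near_cutoff", "clear"))
        out = grp[["individual_id", "population_id", "period"]].copy()
        out["run_id"] = run_id
        out["marker_id"] = assay_id
        out["vaff"] = vaff
        out["dosage"] = dosage
        out["flag"] = flag
        out["cutoff_lower"] = cuts.lower
        out["cutoff_upper"] = cuts.upper
        rows.append(out)
    if not rows:
        return pd.DataFrame(
            columns=["individual_id", "population_id", "period", "run_id",
                     "marker_id", "vaff", "dosage", "flag", "cutoff_lower",
                     "cutoff_upper"]
        )
    return pd.concat(rows, ignore_index=True)


def compute_hybrid_index(
    vaff: float,
    thresholds: tuple[float, float] = HYBRID_THRESHOLDS,
) -> tuple[float, str]:
    """Hybrid index and species category from the pooled multiplex VAFF.

    The multiplex VAFF estimates the robusta ancestry fraction over the 11
    unlinked loci.  Returns ``(value, category)`` with category
    ``pure_intestinalis`` below ``t_low``, ``pure_robusta`` above
    ``t_high``, else ``admixed``; a failed reaction gives
    ``(nan, "missing")``.
    """
    t_low, t_high = thresholds
    if vaff is None or np.isnan(vaff):
        return np.nan, "missing"
    if vaff < t_low:
        return float(vaff), "pure_intestinalis"
    if vaff > t_high:
        return float(vaff), "pure_robusta"
    return float(vaff), "admixed"


def classify_individual(
    hybrid_category: str,
    mito_dosage: float,
) -> dict:
    """Combine nuclear hybrid-index category with the mitochondrial call.

    The mitochondrial assay is effectively haploid: dosage 2 reads as a
    robusta mitotype, 0 as intestinalis, anything else as missing.
    Concordance is defined for non-admixed individuals as nuclear and
    mitochondrial genomes pointing to the same species; admixed
    individuals are always reported (an F1 from a robusta father and
    intestinalis mother shows admixed nuclear + intestinalis mitotype).
    """
    if mito_dosage is None or np.isnan(mito_dosage):
        mito = "missing"
    elif mito_dosage == 2:
        mito = "robusta"
    elif mito_dosage == 0:
        mito = "intestinalis"
    else:
        mito = "missing"  # heterozygous mito signal: treated as failed
    if hybrid_category == "missing" and mito == "missing":
        return {"nuclear_category": "missing", "mito_allele": mito,
                "concordant": False, "classifiable": False}
    concordant = (
        (hybrid_category == "pure_robusta" and mito == "robusta")
        or (hybrid_category == "pure_intestinalis" and mito == "intestinalis")
    )
    return {
        "nuclear_category": hybrid_category,
        "mito_allele": mito,
        "concordant": bool(concordant),
        "classifiable": True,
    }


def build_genotype_matrix(
    fluor: pd.DataFrame,
    panel: Panel,
    exclude_near_cutoff: bool = True,
    **call_kwargs,
) -> GenotypeMatrix:
    """Run the full calling pipeline on a plate table.

    Calls every simplex assay, computes the multiplex hybrid index and the
    species classification, and assembles the individuals × markers
    GenotypeMatrix.  With ``exclude_near_cutoff`` (default), near-cutoff
    dosages are set missing in the matrix; they remain visible in the
    ``call_plate`` output for QC.
    """
    calls = call_plate(fluor, panel, **call_kwargs)
    dosage = calls.pivot_table(
        index="individual_id", columns="marker_id", values="dosage", aggfunc="first"
    )
    if exclude_near_cutoff and len(calls):
        near = calls[calls["flag"] == "near_cutoff"]
        for _, rec in near.iterrows():
            dosage.loc[rec["individual_id"], rec["marker_id"]] = np.nan
    # metadata: population/period per individual
    meta = (
        calls.groupby("individual_id")[["population_id", "period"]].first()
    )
    # multiplex → hybrid index
    mpx = fluor[(fluor["assay_id"] == MULTIPLEX_ASSAY) & ~fluor["is_control"]]
    hi_value = pd.Series(np.nan, index=meta.index, name="hybrid_index")
    hi_cat = pd.Series("missing", index=meta.index, dtype=object)
    for _, rec in mpx.iterrows():
        v = compute_vaff(rec["f1"], rec["f2"])
        value, cat = compute_hybrid_index(v)
        if rec["individual_id"] in hi_value.index:
            hi_value[rec["individual_id"]] = value
            hi_cat[rec["individual_id"]] = cat
    meta["hybrid_index"] = hi_value
    mito_id = panel.mito_marker_id
    species = []
    for ind in meta.index:
        mito_dos = dosage.at[ind, mito_id] if mito_id in dosage.columns else np.nan
        cls = classify_individual(hi_cat[ind], mito_dos)
        species.append(cls["nuclear_category"] if cls["classifiable"] else "unclassified")
    meta["species_class"] = species
    n_admixed = sum(s == "admixed" for s in species)
    if n_admixed:
        logger.info("classified %d admixed individual(s)", n_admixed)
    marker_order = [m for m in panel.simplex_assay_ids if m in dosage.columns]
    return GenotypeMatrix(dosage[marker_order].astype(float), meta)
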