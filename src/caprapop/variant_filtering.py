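"""Two-stage site filtering: multi-caller consensus, then Gaussian recalibration.

Stage 1 merges per-caller call sets and keeps a site when at least two
different callers report it, each with phred-scaled site quality strictly
above 30; among passing sites an alternate allele is retained when any one
caller calls it with at least one non-reference genotype carrying it.

Stage 2 builds a highest-confidence training set (called by all callers with
quality > 100, biallelic, minor allele count ≥ 3 over GQ > 30 genotypes),
fits a multivariate Gaussian to its annotation vectors and another to the
full candidate background, scores every site with the log odds
``VQSLOD = ln N(x; μ_T, Σ_T) − ln N(x; μ_B, Σ_B)``, and removes sites with
``VQSLOD`` below ``median − 3·MAD`` of the training-set scores (MAD unscaled).
Genotypes with posterior probability below 0.95 are masked to missing, never
recoded as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import multivariate_normal

from .io_formats import ANNOTATION_KEYS, Genotype, VariantRecord

SITE_QUAL_MIN = 30.0  # strict: a site at exactly 30 fails
TRAINING_QUAL_MIN = 100.0
TRAINING_GQ_MIN = 30.0
TRAINING_MAC_MIN = 3
GP_MIN = 0.95
MAD_MULTIPLIER = 3.0


class RefMismatchError(ValueError):
    """Callers disagree on the reference allele at a position."""


class InsufficientTrainingError(ValueError):
    """Too few training sites to fit the recalibration Gaussian."""


class NumericError(RuntimeError):
    """Covariance singular even after ridge regularization."""


@dataclass
class MultiCallerSite:
    chrom: str
    pos: int
    ref: str
    records: dict[str, VariantRecord]  # caller_id -> record
    stage1_pass: bool = False
    surviving_alts: tuple[str, ...] = ()
    vqslod: float | None = None
    stage2_pass: bool | None = None

    @property
    def merged_alts(self) -> tuple[str, ...]:
        seen: list[str] = []
        for rec in self.records.values():
            for a in rec.alts:
                if a not in seen:
                    seen.append(a)
        return tuple(seen)


@dataclass
class RecalModel:
    annotations: list[str]
    mu_training: np.ndarray
    cov_training: np.ndarray
    mu_background: np.ndarray
    cov_background: np.ndarray
    training_medians: np.ndarray  # imputation values for missing annotations
    cutoff: float | None = None

    def score(self, x: np.ndarray) -> np.ndarray:
        """VQSLOD for annotation rows ``x``; NaNs imputed with training medians."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x = np.where(np.isnan(x), self.training_medians[None, :], x)
        lt = multivariate_normal(self.mu_training, self.cov_training,
                                 allow_singular=True).logpdf(x)
        lb = multivariate_normal(self.mu_background, self.cov_background,
                                 allow_singular=True).logpdf(x)
        return np.atleast_1d(lt - lb)


def _allele_called(rec: VariantRecord, alt: str) -> bool:
    """True when ``alt`` is in the record and carried by >=1 genotype."""
    if alt not in rec.alts:
        return False
    k = rec.alts.index(alt) + 1
    return any(g.a1 == k or g.a2 == k for g in rec.genotypes)


def stage1_consensus(
    caller_records: dict[str, list[VariantRecord]],
) -> list[MultiCallerSite]:
    """Merge per-caller call sets and apply the consensus pass rules.

    Failing sites are flagged, not deleted.  Callers reporting different
    reference alleles at one position raise :class:`RefMismatchError`.
    """
    grouped: dict[tuple[str, int], dict[str, VariantRecord]] = {}
    for caller, records in caller_records.items():
        for rec in records:
            grouped.setdefault((rec.chrom, rec.pos), {})[caller] = rec
    sites: list[MultiCallerSite] = []
    for (chrom, pos), recs in sorted(grouped.items()):
        refs = {r.ref for r in recs.values()}
        if len(refs) > 1:
            raise RefMismatchError(
                f"{chrom}:{pos}: callers disagree on ref ({sorted(refs)})"
            )
        site = MultiCallerSite(chrom, pos, refs.pop(), recs)
        n_support = sum(r.site_qual > SITE_QUAL_MIN for r in recs.values())
        site.stage1_pass = n_support >= 2
        if site.stage1_pass:
            site.surviving_alts = tuple(
                alt
                for alt in site.merged_alts
                if any(_allele_called(r, alt) for r in recs.values())
            )
        sites.append(site)
    return sites


def _primary_record(site: MultiCallerSite, primary_caller: str) -> VariantRecord:
    if primary_caller in site.records:
        return site.records[primary_caller]
    return next(iter(site.records.values()))


def _minor_allele_count(rec: VariantRecord, gq_min: float = TRAINING_GQ_MIN) -> int:
    n_alt = n_ref = 0
    for g in rec.genotypes:
        if g.missing or g.gq is None or g.gq <= gq_min:
            continue
        n_alt += (g.a1 > 0) + (g.a2 > 0)
        n_ref += (g.a1 == 0) + (g.a2 == 0)
    return min(n_ref, n_alt)


def build_training_set(
    sites: list[MultiCallerSite],
    n_callers: int = 3,
    primary_caller: str | None = None,
    n_annotations: int = len(ANNOTATION_KEYS),
) -> list[MultiCallerSite]:
    """Highest-confidence subset seeding the recalibration Gaussian."""
    if primary_caller is None and sites:
        primary_caller = next(iter(sites[0].records))
    training = []
    for site in sites:
        if len(site.records) < n_callers:
            continue
        if not all(r.site_qual > TRAINING_QUAL_MIN for r in site.records.values()):
            continue
        if len(site.merged_alts) != 1:
            continue
        rec = _primary_record(site, primary_caller)
        if _minor_allele_count(rec) >= TRAINING_MAC_MIN:
            training.append(site)
    if len(training) < 2 * n_annotations:
        raise InsufficientTrainingError(
            f"only {len(training)} training sites; need >= {2 * n_annotations}"
        )
    return training


def _annotation_matrix(
    sites: list[MultiCallerSite], annotations: list[str], primary_caller: str
) -> np.ndarray:
    x = np.full((len(sites), len(annotations)), np.nan)
    for i, site in enumerate(sites):
        rec = _primary_record(site, primary_caller)
        for j, key in enumerate(annotations):
            if key in rec.annotations:
                x[i, j] = rec.annotations[key]
    return x


def _regularized_cov(x: np.ndarray, annotations: list[str],
                     ridge: float) -> np.ndarray:
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov) + ridge * np.eye(x.shape[1])
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0 or eigvals.max() / max(eigvals.min(), 1e-300) > 1e12:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise NumericError(
            "singular annotation covariance after ridge; most collinear pair: "
            f"({annotations[i]}, {annotations[j]})"
        )
    return cov


def fit_recal_model(
    training: list[MultiCallerSite],
    candidates: list[MultiCallerSite],
    annotations: list[str] | None = None,
    primary_caller: str | None = None,
    ridge: float = 1e-6,
) -> RecalModel:
    """Fit training and background Gaussians and score every candidate site.

    Missing annotation values are imputed with the training median of that
    annotation, in both the fit and the scoring.
    """
    if annotations is None:
        annotations = list(ANNOTATION_KEYS)
    if primary_caller is None and training:
        primary_caller = next(iter(training[0].records))
    if len(training) < 2 * len(annotations):
        raise InsufficientTrainingError(
            f"{len(training)} training sites < 2 x {len(annotations)} annotations"
        )
    xt = _annotation_matrix(training, annotations, primary_caller)
    medians = np.nanmedian(xt, axis=0)
    if np.isnan(medians).any():
        bad = annotations[int(np.flatnonzero(np.isnan(medians))[0])]
        raise InsufficientTrainingError(
            f"annotation {bad} missing from every training site"
        )
    xt = np.where(np.isnan(xt), medians[None, :], xt)
    xb = _annotation_matrix(candidates, annotations, primary_caller)
    xb = np.where(np.isnan(xb), medians[None, :], xb)
    model = RecalModel(
        annotations=list(annotations),
        mu_training=xt.mean(axis=0),
        cov_training=_regularized_cov(xt, annotations, ridge),
        mu_background=xb.mean(axis=0),
        cov_background=_regularized_cov(xb, annotations, ridge),
        training_medians=medians,
    )
    scores = model.score(xb)
    for site, s in zip(candidates, scores):
        site.vqslod = float(s)
    if not np.isfinite(scores).all():
        raise NumericError("non-finite VQSLOD produced for a candidate site")
    return model


def vqslod_cutoff(values: np.ndarray | list[float],
                  multiplier: float = MAD_MULTIPLIER) -> float:
    """``median − multiplier × MAD`` of training VQSLOD values, MAD unscaled."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientTrainingError(
            f"need >= 3 VQSLOD values for a cutoff, got {values.size}"
        )
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med - multiplier * mad


def apply_stage2(
    sites: list[MultiCallerSite], model: RecalModel
) -> list[MultiCallerSite]:
    """Keep sites with ``VQSLOD >= cutoff`` (the boundary is retained)."""
    if model.cutoff is None:
        raise ValueError("model has no cutoff; call vqslod_cutoff first")
    retained = []
    for site in sites:
        if site.vqslod is None:
            raise ValueError(f"{site.chrom}:{site.pos} has no VQSLOD score")
        site.stage2_pass = site.vqslod >= model.cutoff
        if site.stage2_pass:
            retained.append(site)
    return retained


def gp_mask(records: list[VariantRecord], gp_min: float = GP_MIN) -> list[VariantRecord]:
    """Mask genotypes with posterior probability strictly below ``gp_min``.

    Masked calls become missing, not reference.  Genotypes without a GP value
    are kept (only an explicit low posterior removes a call).
    """
    out = []
    for rec in records:
        genos = [
            Genotype(-1, -1, g.gq, g.gp)
            if (g.gp is not None and g.gp < gp_min)
            else g
            for g in rec.genotypes
        ]
        out.append(replace(rec, genotypes=genos))
    return out


def run_filter(
    caller_records: dict[str, list[VariantRecord]],
    primary_caller: str | None = None,
    annotations: list[str] | None = None,
    mad_multiplier: float = MAD_MULTIPLIER,
    gp_min: float = GP_MIN,
) -> tuple[list[VariantRecord], dict]:
    """Full two-stage filter; returns GP-masked records of surviving sites
    (primary caller's genotypes) plus a per-stage count report."""
    if primary_caller is None:
        primary_caller = next(iter(caller_records))
    sites = stage1_consensus(caller_records)
    stage1_sites = [s for s in sites if s.stage1_pass]
    training = build_training_set(
        stage1_sites, n_callers=len(caller_records), primary_caller=primary_caller
    )
    model = fit_recal_model(training, stage1_sites, annotations, primary_caller)
    model.cutoff = vqslod_cutoff(
        [s.vqslod for s in training], multiplier=mad_multiplier
    )
    retained = apply_stage2(stage1_sites, model)
    records = [_primary_record(s, primary_caller) for s in retained]
    records = gp_mask(records, gp_min=gp_min)
    report = {
        "n_input_sites": len(sites),
        "n_stage1_pass": len(stage1_sites),
        "n_training": len(training),
        "vqslod_cutoff": model.cutoff,
        "n_stage2_pass": len(retained),
    }
    return records, report
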