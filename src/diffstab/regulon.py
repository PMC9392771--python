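"""RBP / miRNA regulon enrichment over stability-classified genes.

A regulon is the set of transcripts bound by one RNA-binding protein or
miRNA family. Coordinated stability shifts across a regulon indicate changed
regulator activity. Enrichment is tested with a binomial GLM: for each focal
factor, a gene's sites for that factor are "successes" and its sites for all
other factors "failures" (using the total site count as background controls
for covariates like 3' UTR length that inflate binding generally), modelled
against the gene's stability status (-1 destabilized / 0 unchanged /
+1 stabilized) as a numeric trend covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact

from .glm import adjust_bh

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGT")


class RegulonError(ValueError):
    pass


@dataclass
class SiteMatrix:
    """Gene x factor binding-site counts plus per-gene totals."""

    counts: pd.DataFrame  # index gene_id, columns factor_id
    totals: pd.Series     # row sums

    def __post_init__(self) -> None:
        if not np.allclose(self.counts.sum(axis=1), self.totals):
            raise RegulonError("totals do not equal row sums of the site counts")
        if (self.counts.to_numpy() < 0).any():
            raise RegulonError("site counts must be non-negative")


def filter_single_utr_genes(annotation: pd.DataFrame) -> set[str]:
    """Genes whose isoforms all share one single-exon 3' UTR.

    ``annotation`` needs columns ``gene_id``, ``isoform_id``, ``utr_id``,
    ``utr_exon_count``. Restricting to these genes avoids confounding the
    stability signal with alternative 3' UTR usage.
    """
    required = {"gene_id", "isoform_id", "utr_id", "utr_exon_count"}
    if annotation.empty or not required.issubset(annotation.columns):
        raise RegulonError(f"annotation must have columns {sorted(required)}")
    keep = set()
    for gene, grp in annotation.groupby("gene_id"):
        utrs = grp["utr_id"].unique()
        if len(utrs) == 1 and (grp["utr_exon_count"] == 1).all():
            keep.add(gene)
    return keep


def scan_sites(utr_sequence: str, site_sequence: str,
               max_downstream: int = 2000) -> int:
    """Count exact (overlap-allowed) matches of an 8-nt target site in a 3' UTR.

    The UTR is given 5'->3' starting at the first base after the stop codon;
    only matches that fit entirely within the first ``max_downstream``
    nucleotides count (1-based start <= ``max_downstream - 7``). U is
    normalized to T; the site must be target-sense (mRNA strand).
    """
    site = site_sequence.upper().replace("U", "T")
    if len(site) != 8:
        raise RegulonError(f"site sequence must be 8 nt, got {len(site)}")
    if not set(site) <= _VALID_NT:
        raise RegulonError(f"site sequence contains ambiguity codes: {site_sequence!r}")
    seq = utr_sequence.upper().replace("U", "T")[:max_downstream]
    count = 0
    start = seq.find(site)
    while start != -1:
        count += 1
        start = seq.find(site, start + 1)
    return count


def build_site_matrix(
    utrs: dict[str, str] | None = None,
    factor_sites: pd.DataFrame | None = None,
    precomputed: pd.DataFrame | None = None,
    max_downstream: int = 2000,
    binarize: bool = False,
) -> SiteMatrix:
    """Assemble the gene x factor site-count matrix.

    Either scan ``utrs`` (gene_id -> sequence) for the site sequences in
    ``factor_sites`` (columns ``factor_id``, ``site_sequence``; one row per
    site variant), or accept ``precomputed`` per-gene counts (gene_id index,
    factor columns) as given — the form RBP regulons from CLIP data arrive
    in. Factors with zero sites in every gene are excluded with a warning.
    With ``binarize``, multiple sites of one factor in one gene count once
    (presence/absence); by default raw site counts are used.
    """
    if precomputed is not None:
        counts = precomputed.astype(np.int64)
    else:
        if utrs is None or factor_sites is None:
            raise RegulonError("need either precomputed counts or utrs + factor_sites")
        genes = list(utrs)
        factors = list(dict.fromkeys(factor_sites["factor_id"]))
        counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                              columns=factors, dtype=np.int64)
        for _, row in factor_sites.iterrows():
            f, site = row["factor_id"], row["site_sequence"]
            for g in genes:
                counts.loc[g, f] += scan_sites(utrs[g], site, max_downstream)
    if binarize:
        counts = (counts > 0).astype(np.int64)
    empty = counts.columns[(counts.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("excluding %d factor(s) with zero sites everywhere: %s",
                       len(empty), list(empty))
        counts = counts.drop(columns=list(empty))
    return SiteMatrix(counts=counts, totals=counts.sum(axis=1))


def enrichment_glm(factor_counts, totals, status):
    """Binomial GLM of a factor's site share on stability status.

    Returns ``(coefficient, SE, p)`` for the status covariate: the change in
    log-odds that a binding site belongs to the focal factor per unit of
    status. Genes with zero total sites are excluded. On separation or
    non-finite fits, the coefficient is reported as ±inf and the p-value
    falls back to Fisher's exact test on the status-collapsed 2x2 table.
    """
    factor_counts = np.asarray(factor_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    status = np.asarray(status, dtype=float)
    if np.any(factor_counts > totals):
        raise RegulonError("factor site counts exceed totals")
    keep = totals > 0
    y, t, x = factor_counts[keep], totals[keep], status[keep]
    if len(np.unique(x)) < 2:
        raise RegulonError("need at least two distinct status values")
    if y.sum() == 0 or (t - y).sum() == 0:
        return _fisher_fallback(y, t, x, sign=0.0)
    endog = np.column_stack([y, t - y])
    exog = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        coef, se = float(res.params[1]), float(res.bse[1])
        p = float(res.pvalues[1])
        if np.isfinite(coef) and np.isfinite(se) and abs(coef) < 15 and se < 100:
            return coef, se, p
        return _fisher_fallback(y, t, x, sign=np.sign(coef))
    except Exception:
        return _fisher_fallback(y, t, x, sign=0.0)


def _fisher_fallback(y, t, x, sign):
    """Collapse status at its midpoint into a 2x2 table and use Fisher's test."""
    hi = x > np.median(x)
    if hi.all() or (~hi).all():
        hi = x > x.min()
    tab = np.array([
        [y[hi].sum(), (t - y)[hi].sum()],
        [y[~hi].sum(), (t - y)[~hi].sum()],
    ])
    _, p = fisher_exact(tab)
    coef = np.inf * sign if sign else 0.0
    return float(coef), float("inf"), float(p)


def regulon_activity(coefficient: float, direction: str) -> float:
    """Signed regulator-activity score.

    For a stabilizing factor the enrichment coefficient is the activity; for
    a destabilizing factor (binding lowers stability) the sign is inverted so
    that positive activity always means "more active regulator".
    """
    if direction == "stabilizer":
        return float(coefficient)
    if direction == "destabilizer":
        return float(-coefficient)
    raise RegulonError(f"activity undefined for direction {direction!r}")


class RegulonEnrichmentModel:
    """Per-factor enrichment of binding sites along the stability status axis.

    Parameters
    ----------
    sites : SiteMatrix
        Gene x factor binding-site counts.
    status : mapping or Series or array
        Per-gene status in {-1, 0, +1}; aligned on gene IDs when labelled.
    directions : mapping, optional
        factor_id -> {'stabilizer', 'destabilizer'}; factors without a known
        direction get no activity score.
    """

    def __init__(self, sites: SiteMatrix, status, directions=None):
        self.sites = sites
        if isinstance(status, (pd.Series, dict)):
            status = pd.Series(status).reindex(sites.counts.index)
            if status.isna().any():
                raise RegulonError("status missing for some genes in the site matrix")
            status = status.to_numpy()
        self.status = np.asarray(status, dtype=int)
        if len(self.status) != len(sites.counts):
            raise RegulonError("status length does not match site matrix genes")
        self.directions = dict(directions or {})

    def fit(self, fdr: float = 0.05) -> "RegulonEnrichmentResults":
        totals = self.sites.totals.to_numpy()
        rows = []
        for factor in self.sites.counts.columns:
            coef, se, p = enrichment_glm(
                self.sites.counts[factor].to_numpy(), totals, self.status
            )
            direction = self.directions.get(factor, "unknown")
            activity = (
                regulon_activity(coef, direction)
                if direction in ("stabilizer", "destabilizer") and np.isfinite(coef)
                else np.nan
            )
            rows.append({
                "factor_id": factor, "coefficient": coef, "SE": se,
                "pvalue": p, "direction": direction, "activity": activity,
            })
        table = pd.DataFrame(rows)
        table["qvalue"] = adjust_bh(table["pvalue"].to_numpy())
        table = table[["factor_id", "coefficient", "SE", "pvalue", "qvalue",
                       "direction", "activity"]]
        return RegulonEnrichmentResults(table=table, fdr=fdr)


@dataclass
class RegulonEnrichmentResults:
    """Per-factor enrichment table with BH q-values and activity scores."""

    table: pd.DataFrame
    fdr: float

    def summary(self) -> str:
        sig = int((self.table["qvalue"] <= self.fdr).sum())
        return (f"Regulon enrichment: {len(self.table)} factors, "
                f"{sig} significant at q<={self.fdr:g}")
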