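"""Pairwise and multi-site beta-diversity partitioning.

Two index families, each additively split into a turnover and a
nestedness-type component (Baselga's framework):

* incidence-based Sorensen:  beta_sor = beta_sim + beta_nes,
* abundance-based Bray-Curtis:  d_BC = d_BC-bal + d_BC-gra,

where the abundance "balanced variation" and "abundance gradient"
components are the abundance analogues of species turnover and
nestedness.  Pairwise matrices carry the components alongside the total;
multi-site indices are computed over exact pairwise sums (never averages
of pairwise values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CommunityMatrix, DissimilarityMatrix, ValidationError


@dataclass
class MultiSiteBeta:
    """Multi-site dissimilarity and its additive partition.

    ``total = turnover + nestedness``; for the Sorensen family these are
    (beta_SOR, beta_SIM, beta_SNE), for Bray-Curtis
    (beta_BC, beta_BC.BAL, beta_BC.GRA).
    """

    metric: str
    total: float
    turnover: float
    nestedness: float
    n_sites: int

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "total": self.total,
            "turnover": self.turnover,
            "nestedness": self.nestedness,
            "n_sites": self.n_sites,
        }


def _prepare(cm: CommunityMatrix, allow_empty_sites: bool) -> np.ndarray:
    if not allow_empty_sites:
        cm.require_no_empty_sites()
    return np.asarray(cm.counts, dtype=float)


def _pair_abc_incidence(x: np.ndarray):
    """Shared (a) and unique (b, c) taxon counts for every site pair."""
    p = (x > 0).astype(float)
    a = p @ p.T
    rich = p.sum(axis=1)
    b = rich[:, None] - a
    c = rich[None, :] - a
    return a, b, c


def _pair_abc_abundance(x: np.ndarray):
    """Shared abundance A = sum_k min(x_ik, x_jk) and per-site excesses."""
    a = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=-1)
    tot = x.sum(axis=1)
    b = tot[:, None] - a
    c = tot[None, :] - a
    return a, b, c


def _partition(a, b, c, empty):
    """Total/turnover/nestedness matrices from pair components.

    Works identically for incidence (a,b,c) and abundance (A,B,C)
    inputs.  When empty sites are admitted, a pair with one empty site
    keeps total = 1 but gets NaN components (turnover undefined); a pair
    of two empty sites is NaN throughout.
    """
    mn = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = (b + c) / (2 * a + b + c)
        turnover = mn / (a + mn)
    if empty.any():
        one_empty = empty[:, None] ^ empty[None, :]
        both_empty = empty[:, None] & empty[None, :]
        total[one_empty] = 1.0
        total[both_empty] = np.nan
        turnover[one_empty | both_empty] = np.nan
    nestedness = total - turnover
    np.fill_diagonal(total, 0.0)
    np.fill_diagonal(turnover, 0.0)
    np.fill_diagonal(nestedness, 0.0)
    return total, turnover, nestedness


def _pairwise(cm, allow_empty_sites, incidence: bool) -> DissimilarityMatrix:
    x = _prepare(cm, allow_empty_sites)
    empty = x.sum(axis=1) == 0
    if incidence:
        a, b, c = _pair_abc_incidence(x)
        metric, labels = "sorensen", ("beta_sor", "beta_sim", "beta_nes")
    else:
        a, b, c = _pair_abc_abundance(x)
        metric, labels = "braycurtis", ("d_BC", "d_BC-bal", "d_BC-gra")
    total, turnover, nestedness = _partition(a, b, c, empty)
    return DissimilarityMatrix(
        list(cm.site_ids),
        metric,
        total,
        components={"turnover": turnover, "nestedness": nestedness},
        meta={"labels": dict(zip(("total", "turnover", "nestedness"), labels)),
              "allow_nan": bool(empty.any())},
    )


def pairwise_sorensen(cm: CommunityMatrix, allow_empty_sites: bool = False) -> DissimilarityMatrix:
    """Pairwise Sorensen dissimilarity partitioned into turnover and
    nestedness: beta_sor = (b+c)/(2a+b+c), beta_sim = min(b,c)/(a+min(b,c)),
    beta_nes = beta_sor - beta_sim."""
    return _pairwise(cm, allow_empty_sites, incidence=True)


def pairwise_braycurtis(cm: CommunityMatrix, allow_empty_sites: bool = False) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity partitioned into balanced
    variation and abundance gradient components (same algebra as the
    Sorensen partition applied to A = sum min, B, C abundance excesses)."""
    return _pairwise(cm, allow_empty_sites, incidence=False)


def _multisite(cm: CommunityMatrix, incidence: bool) -> MultiSiteBeta:
    x = _prepare(cm, allow_empty_sites=False)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("multi-site beta diversity needs at least 2 sites")
    if incidence:
        a, b, c = _pair_abc_incidence(x)
        p = x > 0
        # K = sum_i S_i - S_T: surplus of site richness over pooled richness
        k = p.sum() - p.any(axis=0).sum()
        metric = "multisite_sorensen"
    else:
        a, b, c = _pair_abc_abundance(x)
        iu = np.triu_indices(n, k=1)
        k = a[iu].sum()
        metric = "multisite_braycurtis"
    iu = np.triu_indices(n, k=1)
    smin = np.minimum(b, c)[iu].sum()
    smax = np.maximum(b, c)[iu].sum()
    turnover = smin / (k + smin)
    total = (smin + smax) / (2 * k + smin + smax)
    return MultiSiteBeta(metric, float(total), float(turnover), float(total - turnover), n)


def multisite_sorensen(cm: CommunityMatrix) -> MultiSiteBeta:
    """Multi-site Sorensen index (beta_SOR) partitioned into beta_SIM and
    beta_SNE, computed from exact sums of pairwise shared/unique taxa."""
    return _multisite(cm, incidence=True)


def multisite_braycurtis(cm: CommunityMatrix) -> MultiSiteBeta:
    """Multi-site Bray-Curtis (beta_BC) partitioned into beta_BC.BAL and
    beta_BC.GRA, from exact sums of pairwise shared abundances."""
    return _multisite(cm, incidence=False)


def component_summary(
    dm: DissimilarityMatrix,
    grouping: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Group-wise means of a partitioned dissimilarity matrix.

    Per group: pair count n(n-1)/2, mean dissimilarity, mean similarity
    (1 - dissimilarity), mean turnover and nestedness components, and
    the turnover share of the total.  ``grouping`` maps site id to a
    group label; ``None`` summarises all sites as one group.
    """
    if "turnover" not in dm.components:
        raise ValidationError("dissimilarity matrix has no partition components")
    ids = np.asarray(dm.site_ids)
    if grouping is None:
        groups = pd.Series("all", index=ids)
    else:
        groups = pd.Series(grouping).reindex(ids)
    rows = []
    for label, members in groups.groupby(groups):
        sel = np.isin(ids, members.index.to_numpy())
        n = int(sel.sum())
        if n < 2:
            warnings.warn(f"group {label!r} has {n} site(s); skipped")
            continue
        sub_idx = np.where(sel)[0]
        iu = np.triu_indices(n, k=1)
        tot = dm.values[np.ix_(sub_idx, sub_idx)][iu]
        tu = dm.components["turnover"][np.ix_(sub_idx, sub_idx)][iu]
        ne = dm.components["nestedness"][np.ix_(sub_idx, sub_idx)][iu]
        ok = ~np.isnan(tot)
        if (~ok).any():
            warnings.warn(f"group {label!r}: {int((~ok).sum())} undefined pairs excluded")
        mean_tot = float(np.mean(tot[ok]))
        rows.append(
            {
                "group": label,
                "n_sites": n,
                "n_pairs": int(ok.sum()),
                "mean_dissimilarity": mean_tot,
                "mean_similarity": 1.0 - mean_tot,
                "mean_turnover": float(np.mean(tu[ok])),
                "mean_nestedness": float(np.mean(ne[ok])),
                "turnover_fraction": float(np.mean(tu[ok]) / mean_tot) if mean_tot > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
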