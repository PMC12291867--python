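"""Null-model stochasticity ratios (ST, NST, MST) for community assembly.

The "PF" null model randomises a community matrix holding each site's
richness Fixed while drawing taxa with Probability proportional to their
regional occupancy frequency; the drawn taxa then share the site's
observed total abundance via a multinomial with probabilities
proportional to regional mean relative abundances.  Comparing observed
pairwise Bray-Curtis dissimilarity D with its null expectation E (mean
over draws) yields per-pair stochasticity ratios:

* ST   — similarity-ratio form: null/observed similarity when the
  observed pair is more similar than the null expects, otherwise
  null/observed dissimilarity; 1 = fully stochastic.
* NST  — approximate reconstruction of the normalised ratio,
  ``1 - (D - E)/(D_max - E)``; unbounded above 1 when D < E, which is
  exactly the behaviour that motivates the modified form.
* MST  — modified (bounded) ratio: ``D/E`` when D <= E, else
  ``(D_max - D)/(D_max - E)``; MST in [0, 1], equal to 1 when the
  observed dissimilarity matches the null, shrinking toward 0 at both
  deterministic extremes.  Pairs with MST > 0.5 are read as
  stochasticity-dominated, MST < 0.5 as determinism-dominated.

D_max = 1 for Bray-Curtis.  The exact published NST normalisation is
not reproduced here; outputs carry ``formula_source`` so downstream
users can trace which form produced them.  Headline classifications use
MST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta_diversity import pairwise_braycurtis
from .core_io import CommunityMatrix, DissimilarityMatrix, ValidationError

D_MAX = 1.0  # Bray-Curtis upper bound
FORMULA_SOURCE = "betadrivers approximate reconstruction (MST bounded form)"


@dataclass
class NullEnsemble:
    """Observed Bray-Curtis and its null distribution per site pair."""

    site_ids: list[str]
    observed: np.ndarray  # square matrix D
    null_mean: np.ndarray  # square matrix E (mean over draws)
    n_draws: int
    seed: int
    formula_source: str = FORMULA_SOURCE


def _check_constraints(null_counts: np.ndarray, richness: np.ndarray, totals: np.ndarray) -> None:
    if not np.array_equal((null_counts > 0).sum(axis=1), richness):
        raise AssertionError("null draw violated per-site richness constraint")
    if not np.array_equal(null_counts.sum(axis=1), totals):
        raise AssertionError("null draw violated per-site total-abundance constraint")


def null_model_pf(
    cm: CommunityMatrix,
    n_draws: int = 1000,
    seed: int = 0,
    check_constraints: bool = True,
) -> NullEnsemble:
    """PF-null ensemble of Bray-Curtis dissimilarities.

    Every draw preserves each site's observed richness and total
    abundance exactly (asserted per draw unless disabled); taxa are
    included with probability proportional to regional occupancy
    frequency and abundances assigned multinomially with probabilities
    proportional to regional mean relative abundance.
    """
    cm.require_no_empty_sites()
    rng = np.random.default_rng(seed)
    x = np.asarray(cm.counts, dtype=np.int64)
    n_sites, n_taxa = x.shape
    presence = x > 0
    richness = presence.sum(axis=1)
    totals = x.sum(axis=1)
    occupancy = presence.sum(axis=0).astype(float)
    if (richness > (occupancy > 0).sum()).any():
        raise ValidationError("site richness exceeds regional richness")
    rel = x / totals[:, None]
    mean_rel = rel.mean(axis=0)

    pool = np.flatnonzero(occupancy > 0)
    p_incl = occupancy[pool] / occupancy[pool].sum()

    obs = pairwise_braycurtis(cm).values
    acc = np.zeros((n_sites, n_sites))
    for _ in range(n_draws):
        null = np.zeros((n_sites, n_taxa), dtype=np.int64)
        for s in range(n_sites):
            chosen = rng.choice(pool, size=richness[s], replace=False, p=p_incl)
            w = mean_rel[chosen]
            if w.sum() == 0:
                w = np.ones_like(w)
            w = w / w.sum()
            if richness[s] == 1:
                null[s, chosen[0]] = totals[s]
                continue
            # every drawn taxon must occur: give each one individual,
            # then distribute the rest multinomially
            alloc = rng.multinomial(totals[s] - richness[s], w)
            null[s, chosen] = alloc + 1
        if check_constraints:
            _check_constraints(null, richness, totals)
        null_cm = CommunityMatrix(list(cm.site_ids), list(cm.taxon_ids), null)
        acc += pairwise_braycurtis(null_cm).values
    return NullEnsemble(list(cm.site_ids), obs, acc / n_draws, n_draws, seed)


def _pair_ratio(d: np.ndarray, e: np.ndarray, kind: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    out = np.ones_like(d)
    if kind == "st":
        c, ec = 1.0 - d, 1.0 - e
        sim_branch = c >= ec  # observed more similar than null expectation
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(sim_branch, ec / c, e / d)
        out[(c == 0) & (ec == 0)] = 1.0
        out[(d == 0) & (e == 0)] = 1.0
    elif kind == "mst":
        with np.errstate(divide="ignore", invalid="ignore"):
            lower = d / e
            upper = (D_MAX - d) / (D_MAX - e)
        out = np.where(d <= e, lower, upper)
        out[(d == 0) & (e == 0)] = 1.0
        out[(d == D_MAX) & (e == D_MAX)] = 1.0
    elif kind == "nst":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 - (d - e) / (D_MAX - e)
        out[(d == D_MAX) & (e == D_MAX)] = 1.0
    else:  # pragma: no cover
        raise ValueError(kind)
    return np.nan_to_num(out, nan=1.0, posinf=1.0, neginf=0.0)


def _ratio_matrix(ensemble: NullEnsemble, kind: str, metric: str) -> DissimilarityMatrix:
    vals = _pair_ratio(ensemble.observed, ensemble.null_mean, kind)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DissimilarityMatrix(
        list(ensemble.site_ids), metric, vals,
        meta={"formula_source": ensemble.formula_source, "n_draws": ensemble.n_draws},
    )


def st_pairwise(ensemble: NullEnsemble) -> DissimilarityMatrix:
    """Similarity-ratio stochasticity ST in [0, 1] per site pair."""
    return _ratio_matrix(ensemble, "st", "ST")


def nst_pairwise(ensemble: NullEnsemble) -> DissimilarityMatrix:
    """Approximate NST reconstruction (can exceed 1; see module docs)."""
    return _ratio_matrix(ensemble, "nst", "NST_approx")


def mst_pairwise(ensemble: NullEnsemble) -> DissimilarityMatrix:
    """Modified stochasticity ratio MST in [0, 1] per site pair."""
    return _ratio_matrix(ensemble, "mst", "MST")


@dataclass
class StochasticityResult:
    """Group summaries of the MST classification."""

    table: pd.DataFrame
    formula_source: str = FORMULA_SOURCE


def group_summary(
    mst: DissimilarityMatrix,
    grouping: pd.Series | dict | None = None,
    tie_tol: float = 1e-12,
) -> StochasticityResult:
    """Per-group mean MST and stochastic/deterministic pair shares.

    A pair is stochastic when MST > 0.5 and deterministic when
    MST < 0.5; exact ties (within ``tie_tol``) count as stochastic, so
    the two shares always sum to 1.
    """
    ids = np.asarray(mst.site_ids)
    groups = pd.Series("all", index=ids) if grouping is None else pd.Series(grouping).reindex(ids)
    rows = []
    for label, members in groups.groupby(groups):
        sel = np.where(np.isin(ids, members.index.to_numpy()))[0]
        n = len(sel)
        if n < 2:
            warnings.warn(f"group {label!r} has {n} site(s); skipped")
            continue
        iu = np.triu_indices(n, k=1)
        vals = mst.values[np.ix_(sel, sel)][iu]
        stochastic = vals >= 0.5 - tie_tol
        rows.append(
            {
                "group": label,
                "n_sites": n,
                "n_pairs": len(vals),
                "mean_mst": float(vals.mean()),
                "median_mst": float(np.median(vals)),
                "stochastic_share": float(stochastic.mean()),
                "deterministic_share": float(1.0 - stochastic.mean()),
            }
        )
    return StochasticityResult(pd.DataFrame(rows).set_index("group"))
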