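"""Population-level statistics of replisome focus localization.

Turns per-cell, per-frame focus lists into the quantities that distinguish
a replication "factory" (co-localized sister forks, one diffraction-limited
focus per fork pair) from independently tracking forks:

* all unique within-cell long-axis focus separations, relative to cell
  length;
* a two-component Gaussian mixture over those relative separations,
  separating transiently resolved sister forks (low separation, ~0.2 cell
  lengths) from pairs of distinct factories near the quarter-cell positions
  (high separation, ~0.45 cell lengths);
* per-cell factory counts: every focus that is not one of a resolved-sister
  pair is itself a co-localized fork pair, so
  ``n_coloc = n_foci - 2 * n_resolved_pairs``;
* the population co-localized fraction, the conditional position density
  given cell length, and localization-pattern frequencies by length.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "SeparationMixture",
    "pair_separations",
    "fit_mixture",
    "classify_pairs",
    "count_factories",
    "colocalization_fraction",
    "conditional_position_density",
    "pattern_frequencies",
]

MIN_PAIRS_FOR_MIXTURE = 50
RESOLVED_SISTER_BOUND = 0.33  # resolved sisters stay under a third of the cell


@dataclass
class SeparationMixture:
    """Two-Gaussian mixture over relative focus separations.

    Components are ordered so ``mu_low < mu_high``; ``w_low + w_high == 1``.
    """

    mu_low: float
    sd_low: float
    w_low: float
    mu_high: float
    sd_high: float
    w_high: float
    loglik: float
    n_iter: int
    n_samples: int

    def posterior_low(self, x) -> np.ndarray:
        """P(low-separation component | x)."""
        x = np.asarray(x, dtype=float)
        lo = np.log(self.w_low) + norm.logpdf(x, self.mu_low, self.sd_low)
        hi = np.log(self.w_high) + norm.logpdf(x, self.mu_high, self.sd_high)
        with np.errstate(invalid="ignore"):
            post = np.exp(lo - np.logaddexp(lo, hi))
        return np.nan_to_num(post, nan=0.0)

    def to_dict(self) -> dict:
        return {k: float(v) if not isinstance(v, int) else v
                for k, v in self.__dict__.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def pair_separations(foci: pd.DataFrame) -> pd.DataFrame:
    """All unique within-cell-frame focus pairs and their separations.

    ``foci`` must carry ``frame``, ``cell_id``, ``rel_pos`` and
    ``length_um`` columns (retained foci only).  Returns one row per
    unordered pair with the long-axis separation in um and relative to the
    cell length; cells with fewer than two foci contribute nothing.
    """
    rows = []
    if len(foci) == 0:
        return pd.DataFrame(columns=["cell_id", "frame", "i", "j", "sep_um",
                                     "rel_sep", "length_um"])
    for (frame, cell), grp in foci.groupby(["frame", "cell_id"]):
        if len(grp) < 2:
            continue
        idx = grp.index.to_numpy()
        rel = grp.rel_pos.to_numpy()
        L = float(grp.length_um.iloc[0])
        for a, b in itertools.combinations(range(len(idx)), 2):
            rel_sep = abs(rel[a] - rel[b])
            rows.append((int(cell), int(frame), int(idx[a]), int(idx[b]),
                         rel_sep * L, rel_sep, L))
    return pd.DataFrame(
        rows, columns=["cell_id", "frame", "i", "j", "sep_um", "rel_sep",
                       "length_um"])


def _em_once(x, mu, sd, w, max_iter=2000, tol=1e-8):
    n = len(x)
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        logp = np.stack([
            np.log(w[k]) + norm.logpdf(x, mu[k], sd[k]) for k in range(2)])
        ll = float(logsumexp(logp, axis=0).sum())
        r = np.exp(logp - logsumexp(logp, axis=0))
        nk = r.sum(axis=1)
        if np.any(nk < 1e-10):
            return mu, sd, w, -np.inf, it, False
        mu = (r @ x) / nk
        var = np.array([r[k] @ (x - mu[k]) ** 2 / nk[k] for k in range(2)])
        sd = np.sqrt(var)
        w = nk / n
        if np.any(sd < 1e-4):
            return mu, sd, w, ll, it, False  # degenerate spike
        if abs(ll - ll_prev) < tol:
            return mu, sd, w, ll, it, True
        ll_prev = ll
    return mu, sd, w, ll_prev, it, True


def fit_mixture(rel_seps, seed: int = 0,
                max_restarts: int = 10) -> SeparationMixture:
    """Maximum-likelihood two-Gaussian mixture via EM.

    Initialization is k-means-like (split at the median); a degenerate
    component triggers a jittered restart, up to ``max_restarts`` times.
    Requires at least 50 separations.
    """
    x = np.asarray(rel_seps, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_PAIRS_FOR_MIXTURE:
        raise ValueError(
            f"need at least {MIN_PAIRS_FOR_MIXTURE} focus pairs to fit the "
            f"mixture, got {len(x)}")
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    w = np.array([0.5, 0.5])
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        m, s, ww, ll, it, okflag = _em_once(x, mu.copy(), sd.copy(), w.copy())
        if okflag:
            best = (m, s, ww, ll, it)
            break
        # degenerate component: restart from jittered data points
        mu = np.sort(x[rng.integers(0, len(x), size=2)]
                     + rng.normal(0, 1e-3, size=2))
        sd = np.array([max(x.std() / 2, 1e-3)] * 2)
        w = np.array([0.5, 0.5])
    if best is None:
        raise RuntimeError("mixture fit failed to converge without "
                           "degenerate components")
    m, s, ww, ll, it = best
    order = np.argsort(m)
    m, s, ww = m[order], s[order], ww[order]
    return SeparationMixture(
        mu_low=float(m[0]), sd_low=float(s[0]), w_low=float(ww[0]),
        mu_high=float(m[1]), sd_high=float(s[1]), w_high=float(ww[1]),
        loglik=ll, n_iter=it, n_samples=len(x))


def classify_pairs(pairs: pd.DataFrame,
                   mixture: SeparationMixture) -> pd.DataFrame:
    """Label focus pairs and pick a disjoint set of resolved-sister pairs.

    Every pair gets the posterior probability of the low-separation
    component.  Pairs with posterior > 0.5 are resolved-sister candidates;
    within each cell-frame, candidates are accepted greedily in decreasing
    posterior subject to each focus belonging to at most one accepted pair.
    Accepted pairs are labeled ``resolved_sisters``; everything else is
    ``high_separation``.
    """
    out = pairs.copy()
    if len(out) == 0:
        out["posterior_low"] = pd.Series(dtype=float)
        out["label"] = pd.Series(dtype=object)
        out["accepted"] = pd.Series(dtype=bool)
        return out
    out["posterior_low"] = mixture.posterior_low(out.rel_sep.to_numpy())
    accepted = np.zeros(len(out), dtype=bool)
    for _, grp in out.groupby(["frame", "cell_id"]):
        cands = grp[grp.posterior_low > 0.5]
        used: set[int] = set()
        for ridx in cands.sort_values(
                "posterior_low", ascending=False, kind="stable").index:
            i, j = int(out.at[ridx, "i"]), int(out.at[ridx, "j"])
            if i in used or j in used:
                continue
            used.update((i, j))
            accepted[out.index.get_loc(ridx)] = True
    out["accepted"] = accepted
    out["label"] = np.where(accepted, "resolved_sisters", "high_separation")
    return out


def count_factories(foci: pd.DataFrame, classified_pairs: pd.DataFrame,
                    cell_frames: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per cell-frame fork-pair bookkeeping.

    Each accepted resolved-sister pair accounts for two foci (one per
    sister); every remaining focus is a co-localized pair, so
    ``n_coloc = n_foci - 2 * n_resolved``.  ``cell_frames`` (columns
    cell_id, frame, length_um) optionally adds zero-focus cell-frames,
    which contribute no pairs but matter for pattern frequencies.
    """
    counts = (foci.groupby(["frame", "cell_id"]).agg(
        n_foci=("cell_id", "size"), length_um=("length_um", "first"))
        .reset_index())
    acc = classified_pairs[classified_pairs.accepted] if len(classified_pairs) \
        else classified_pairs
    if len(acc):
        focus_ids = set(foci.index)
        bad = acc[~(acc.i.isin(focus_ids) & acc.j.isin(focus_ids))]
        if len(bad):
            raise ValueError("classified pairs reference foci missing from "
                             "the focus table")
        nres = acc.groupby(["frame", "cell_id"]).size().rename("n_resolved")
        counts = counts.merge(nres, on=["frame", "cell_id"], how="left")
        counts["n_resolved"] = counts.n_resolved.fillna(0).astype(int)
    else:
        counts["n_resolved"] = 0
    counts["n_coloc"] = counts.n_foci - 2 * counts.n_resolved
    if (counts.n_coloc < 0).any():
        raise ValueError("inconsistent counts: more resolved sisters than foci")
    if cell_frames is not None:
        key = counts.set_index(["frame", "cell_id"]).index
        extra = cell_frames[~cell_frames.set_index(
            ["frame", "cell_id"]).index.isin(key)].copy()
        extra = extra.assign(n_foci=0, n_resolved=0, n_coloc=0)
        counts = pd.concat(
            [counts, extra[["frame", "cell_id", "n_foci", "length_um",
                            "n_resolved", "n_coloc"]]],
            ignore_index=True).sort_values(
                ["frame", "cell_id"], ignore_index=True)
    return counts


def colocalization_fraction(counts: pd.DataFrame) -> float:
    """Fraction of fork pairs that are co-localized, over the whole dataset."""
    n_coloc = int(counts.n_coloc.sum())
    n_res = int(counts.n_resolved.sum())
    if n_coloc + n_res == 0:
        raise ValueError("no fork pairs observed")
    return n_coloc / (n_coloc + n_res)


def conditional_position_density(rel_pos, lengths_um,
                                 length_bin_um: float = 0.25,
                                 pos_bin: float = 0.02,
                                 length_range=None):
    """P(relative position | cell length) as a column-stochastic matrix.

    Returns ``(matrix, pos_edges, length_edges)``; each column (one length
    bin) sums to 1 unless empty.
    """
    rel_pos = np.asarray(rel_pos, dtype=float)
    lengths = np.asarray(lengths_um, dtype=float)
    if length_range is None:
        lo = math.floor(lengths.min() / length_bin_um) * length_bin_um
        hi = math.ceil(lengths.max() / length_bin_um) * length_bin_um
        if hi <= lo:  # all lengths in one bin
            hi = lo + length_bin_um
        length_range = (lo, hi)
    length_edges = np.arange(length_range[0],
                             length_range[1] + length_bin_um / 2, length_bin_um)
    pos_edges = np.arange(0.0, 1.0 + pos_bin / 2, pos_bin)
    H, _, _ = np.histogram2d(rel_pos, lengths, bins=(pos_edges, length_edges))
    colsum = H.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(colsum > 0, H / colsum, 0.0)
    return M, pos_edges, length_edges


def _pattern_of(n_foci: int, n_resolved: int) -> str:
    if n_foci == 0:
        return "0_foci"
    if n_foci == 1:
        return "1_focus"
    if n_foci == 2:
        return "2_resolved_pair" if n_resolved == 1 else "2_two_pairs"
    if n_foci == 3:
        return "3_foci"
    return "4plus_foci"


PATTERNS = ["0_foci", "1_focus", "2_resolved_pair", "2_two_pairs",
            "3_foci", "4plus_foci"]


def pattern_frequencies(counts: pd.DataFrame,
                        length_bin_um: float | None = 0.25) -> pd.DataFrame:
    """Localization-pattern frequencies, overall and per length bin.

    Rows are patterns; there is one ``overall`` column plus one column per
    cell-length bin, each column summing to 1 over the observed patterns.
    """
    pat = [
        _pattern_of(int(n), int(r))
        for n, r in zip(counts.n_foci, counts.n_resolved)
    ]
    df = counts.assign(pattern=pd.Categorical(pat, categories=PATTERNS))
    table = {"overall": df.pattern.value_counts(normalize=True, sort=False)}
    if length_bin_um:
        lo = math.floor(df.length_um.min() / length_bin_um) * length_bin_um
        hi = math.ceil(df.length_um.max() / length_bin_um) * length_bin_um
        edges = np.arange(lo, hi + length_bin_um / 2, length_bin_um)
        binned = pd.cut(df.length_um, edges)
        for interval, grp in df.groupby(binned, observed=True):
            if len(grp):
                table[f"L_{interval.left:.2f}_{interval.right:.2f}"] = (
                    grp.pattern.value_counts(normalize=True, sort=False))
    return pd.DataFrame(table).fillna(0.0)
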