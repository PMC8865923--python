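"""Distance computation and multi-factor permutational variance partitioning.

Implements PERMANOVA from first principles: Gower-centered inner-product
matrix, sequential (Type I) sums of squares via nested design projections,
pseudo-F per term, and permutation p-values with optional strata.

Strata semantics: labels are shuffled only within strata blocks; when the
tested factor is constant within blocks (e.g., disease status within a
participant) within-block shuffles cannot test it, so whole blocks of equal
size are exchanged instead. The fallback is logged prominently.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth

from .datatypes import TRANSFORMED_RELABUND, AsvTable

logger = logging.getLogger(__name__)

EXACT_GUARD = 10**6

SCHEME_FREE = "free"
SCHEME_WITHIN = "within_strata"
SCHEME_BLOCKS = "block_exchange"


class DesignError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("distance matrix not symmetric (tolerance 1e-12)")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)])


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)."""
    x = table.values
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        den = (x[i] + x[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(den > 0, num / den, 0.0)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(list(table.sample_ids), d)


def jaccard_binary(table: AsvTable) -> DistanceMatrix:
    """1 - Jaccard membership similarity on detection (presence/absence)."""
    b = (table.values > 0).astype(float)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d)


def euclidean(table_or_values, sample_ids: list[str] | None = None) -> DistanceMatrix:
    if isinstance(table_or_values, AsvTable):
        x = table_or_values.values
        sample_ids = list(table_or_values.sample_ids)
    else:
        x = np.atleast_2d(np.asarray(table_or_values, dtype=float))
        if x.shape[0] == 1:
            x = x.T
        if sample_ids is None:
            sample_ids = [str(i) for i in range(x.shape[0])]
    sq = (x**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * (x @ x.T), 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(sample_ids, d)


METRICS = {
    "bray_curtis": bray_curtis,
    "jaccard_binary": jaccard_binary,
    "euclidean": euclidean,
}


def compute_distance(table: AsvTable, metric: str = "bray_curtis") -> DistanceMatrix:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if metric == "bray_curtis" and table.value_kind != TRANSFORMED_RELABUND:
        logger.warning("Bray-Curtis computed on non-normalized values")
    return METRICS[metric](table)


def gower_center(d: DistanceMatrix) -> np.ndarray:
    """G = -1/2 * J A J with A the squared distances and J = I - 11'/n.

    trace(G) equals the total sum of squares sum_{i<j} d_ij^2 / n.
    """
    a = d.values**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * (j @ a @ j)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _term_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Columns encoding one model term.

    Float columns are treated as continuous (centered single column);
    everything else is categorical and expands to one indicator per level
    (redundancy absorbed downstream by projection rank).
    """
    if term not in meta.columns:
        raise DesignError(f"term {term!r} not in metadata")
    v = meta[term]
    if v.isna().any():
        raise DesignError(f"term {term!r} has missing values in the model subset")
    if pd.api.types.is_float_dtype(v):
        if v.nunique() < 2:
            raise DesignError(f"no variation in term {term!r}")
        col = v.to_numpy(dtype=float)
        return (col - col.mean())[:, None]
    vals = v.astype(str).to_numpy()
    levels = sorted(set(vals))
    if len(levels) < 2:
        raise DesignError(f"no variation in term {term!r}")
    return np.column_stack([(vals == lev).astype(float) for lev in levels])


def _nested_projectors(meta: pd.DataFrame, terms: list[str]) -> tuple[list[np.ndarray], list[int]]:
    """Hat matrices of the nested designs (intercept, +term1, +term1+term2, ...)
    and the rank increment (df) contributed by each term."""
    n = len(meta)
    x = np.ones((n, 1))
    q = orth(x)
    hats = [q @ q.T]
    ranks = [1]
    for term in terms:
        x = np.hstack([x, _term_matrix(meta, term)])
        q = orth(x)
        hats.append(q @ q.T)
        ranks.append(q.shape[1])
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    return hats, dfs


# ---------------------------------------------------------------------------
# Permutation schemes
# ---------------------------------------------------------------------------

def _blocks_from_strata(meta: pd.DataFrame, strata: str) -> list[np.ndarray]:
    codes = meta[strata].astype(str).to_numpy()
    blocks = []
    for lev in pd.unique(codes):
        blocks.append(np.flatnonzero(codes == lev))
    return blocks


def _is_block_constant(meta: pd.DataFrame, term: str, strata: str) -> bool:
    return bool((meta.groupby(meta[strata].astype(str))[term].nunique() <= 1).all())


def _count_exact(scheme: str, n: int, blocks: list[np.ndarray] | None) -> int:
    if scheme == SCHEME_FREE:
        return math.factorial(n)
    if scheme == SCHEME_WITHIN:
        total = 1
        for b in blocks:
            total *= math.factorial(len(b))
        return total
    sizes = {}
    for b in blocks:
        sizes.setdefault(len(b), 0)
        sizes[len(b)] += 1
    total = 1
    for m in sizes.values():
        total *= math.factorial(m)
    return total


def _enumerate_perms(scheme: str, n: int, blocks: list[np.ndarray] | None):
    if scheme == SCHEME_FREE:
        for p in itertools.permutations(range(n)):
            yield np.array(p)
        return
    if scheme == SCHEME_WITHIN:
        per_block = [list(itertools.permutations(b)) for b in blocks]
        for combo in itertools.product(*per_block):
            perm = np.empty(n, dtype=int)
            for b, arrangement in zip(blocks, combo):
                perm[b] = arrangement
            yield perm
        return
    # block exchange: permute whole blocks within equal-size classes
    by_size: dict[int, list[int]] = {}
    for bi, b in enumerate(blocks):
        by_size.setdefault(len(b), []).append(bi)
    classes = list(by_size.values())
    per_class = [list(itertools.permutations(c)) for c in classes]
    for combo in itertools.product(*per_class):
        perm = np.empty(n, dtype=int)
        for cls, arrangement in zip(classes, combo):
            for src, dst in zip(cls, arrangement):
                perm[blocks[src]] = blocks[dst]
        yield perm


def _draw_perm(rng: np.random.Generator, scheme: str, n: int, blocks) -> np.ndarray:
    if scheme == SCHEME_FREE:
        return rng.permutation(n)
    perm = np.arange(n)
    if scheme == SCHEME_WITHIN:
        for b in blocks:
            perm[b] = rng.permutation(b)
        return perm
    by_size: dict[int, list[int]] = {}
    for bi, b in enumerate(blocks):
        by_size.setdefault(len(b), []).append(bi)
    for cls in by_size.values():
        shuffled = rng.permutation(cls)
        for src, dst in zip(cls, shuffled):
            perm[blocks[src]] = blocks[dst]
    return perm


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class TermResult:
    term: str
    df: int
    ss: float
    r_squared: float
    pseudo_f: float
    p_value: float
    scheme: str
    aliased: bool = False


@dataclass
class PermanovaResult:
    terms: list[TermResult]
    residual_df: int
    residual_ss: float
    residual_r_squared: float
    total_ss: float
    n_permutations: int | str
    strata: str | None
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ss_sum = sum(t.ss for t in self.terms) + self.residual_ss
        if self.total_ss > 0 and abs(ss_sum - self.total_ss) > 1e-9 * max(1.0, self.total_ss):
            raise AssertionError("sums of squares do not add to total")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.term, "df": t.df, "sum_of_squares": t.ss,
                "r_squared": t.r_squared, "pseudo_F": t.pseudo_f,
                "p_value": t.p_value, "permutation_scheme": t.scheme,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual", "df": self.residual_df,
                "sum_of_squares": self.residual_ss,
                "r_squared": self.residual_r_squared,
                "pseudo_F": np.nan, "p_value": np.nan, "permutation_scheme": "",
            }
        )
        rows.append(
            {
                "term": "Total",
                "df": self.residual_df + sum(t.df for t in self.terms),
                "sum_of_squares": self.total_ss, "r_squared": 1.0,
                "pseudo_F": np.nan, "p_value": np.nan, "permutation_scheme": "",
            }
        )
        return pd.DataFrame(rows)

    def term_map(self) -> dict[str, TermResult]:
        return {t.term: t for t in self.terms}


def _f_ge(a: float, b: float) -> bool:
    """Tie-tolerant comparison a >= b for pseudo-F values."""
    if np.isnan(a) or np.isnan(b):
        return False
    if np.isinf(b):
        return bool(np.isinf(a) and a > 0)
    return a >= b - 1e-12 * max(1.0, abs(b))


def _stage_ss(hats: list[np.ndarray], g: np.ndarray, total_ss: float) -> tuple[np.ndarray, float]:
    """Sequential term SS and residual SS for a (possibly permuted) G."""
    traces = np.array([np.vdot(h, g) for h in hats])
    term_ss = np.diff(traces)
    ss_model = traces[-1] - traces[0]
    ss_res = total_ss - ss_model
    return term_ss, ss_res


def permanova(
    d: DistanceMatrix,
    meta: pd.DataFrame,
    terms: list[str],
    n_perm: int | str = 999,
    strata: str | None = None,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential multi-factor PERMANOVA on a distance matrix.

    Parameters
    ----------
    d : DistanceMatrix
    meta : DataFrame
        One row per sample, aligned to ``d.sample_ids`` (reordered here).
    terms : list of metadata columns, fitted in order (Type I SS).
    n_perm : int or "exact"
        Monte-Carlo permutation count, or exhaustive enumeration ("exact",
        guarded above 10^6 arrangements). p-values use the add-one
        estimator for Monte Carlo and the exact proportion (identity
        included) for enumeration.
    strata : metadata column or None
        Restrict permutations to within-stratum shuffles; a term constant
        within strata is tested by exchanging whole equal-size blocks.
    seed : int or None
        Seeds the permutation stream; identical seed gives identical p.
    """
    if d.n < 3:
        raise ValueError("need at least 3 samples")
    if not terms:
        raise ValueError("need at least one term")
    meta = meta.set_index(meta["sample_id"].astype(str)).loc[d.sample_ids]
    n = d.n

    for term in terms:
        col = meta[term]
        nun = col.astype(str).nunique() if not pd.api.types.is_float_dtype(col) else col.nunique()
        if nun < 2:
            raise DesignError(f"no variation in term {term!r}")

    g = gower_center(d)
    total_ss = float(np.trace(g))
    hats, dfs = _nested_projectors(meta, terms)
    df_model = sum(dfs)
    df_res = n - 1 - df_model
    if df_res < 0:
        raise DesignError("singular design: residual degrees of freedom < 0")

    term_ss, ss_res = _stage_ss(hats, g, total_ss)

    warnings_: list[str] = []

    def f_stats(t_ss: np.ndarray, s_res: float) -> np.ndarray:
        out = np.full(len(terms), np.nan)
        for k, df_k in enumerate(dfs):
            if df_k == 0:
                continue
            if df_res > 0 and s_res > 1e-12 * max(1.0, total_ss):
                out[k] = (t_ss[k] / df_k) / (s_res / df_res)
            else:
                out[k] = np.inf if t_ss[k] > 0 else np.nan
        return out

    f_obs = f_stats(term_ss, ss_res)

    # permutation schemes per term
    blocks = _blocks_from_strata(meta, strata) if strata else None
    schemes = []
    for term in terms:
        if strata is None:
            schemes.append(SCHEME_FREE)
        elif _is_block_constant(meta, term, strata):
            schemes.append(SCHEME_BLOCKS)
            msg = (
                f"term {term!r} is constant within strata {strata!r}: "
                "within-block shuffles cannot test it; exchanging whole "
                "equal-size blocks instead"
            )
            logger.warning(msg)
            warnings_.append(msg)
        else:
            schemes.append(SCHEME_WITHIN)

    exact = n_perm == "exact"
    if not exact:
        n_perm = int(n_perm)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1 or 'exact'")

    p_values = np.full(len(terms), np.nan)
    counts = np.zeros(len(terms))
    scheme_groups: dict[str, list[int]] = {}
    for k, sch in enumerate(schemes):
        scheme_groups.setdefault(sch, []).append(k)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(scheme_groups))

    for gi, (sch, term_idx) in enumerate(sorted(scheme_groups.items())):
        testable = [k for k in term_idx if dfs[k] > 0 and not np.isnan(f_obs[k])]
        if not testable:
            continue
        if exact:
            n_arr = _count_exact(sch, n, blocks)
            if n_arr > EXACT_GUARD:
                raise ValueError(
                    f"exact enumeration needs {n_arr} arrangements "
                    f"(> {EXACT_GUARD}); use Monte Carlo n_perm"
                )
            if n_arr <= 1:
                msg = f"scheme {sch}: no exchangeable arrangements; p undefined"
                logger.warning(msg)
                warnings_.append(msg)
                continue
            total = 0
            for perm in _enumerate_perms(sch, n, blocks):
                gp = g[np.ix_(perm, perm)]
                t_ss_p, s_res_p = _stage_ss(hats, gp, total_ss)
                f_p = f_stats(t_ss_p, s_res_p)
                for k in testable:
                    if _f_ge(f_p[k], f_obs[k]):
                        counts[k] += 1
                total += 1
            for k in testable:
                p_values[k] = counts[k] / total
        else:
            rng = np.random.default_rng(children[gi])
            for _ in range(n_perm):
                perm = _draw_perm(rng, sch, n, blocks)
                gp = g[np.ix_(perm, perm)]
                t_ss_p, s_res_p = _stage_ss(hats, gp, total_ss)
                f_p = f_stats(t_ss_p, s_res_p)
                for k in testable:
                    if _f_ge(f_p[k], f_obs[k]):
                        counts[k] += 1
            for k in testable:
                p_values[k] = (1.0 + counts[k]) / (1.0 + n_perm)

    term_results = []
    for k, term in enumerate(terms):
        aliased = dfs[k] == 0
        if aliased:
            msg = f"term {term!r} is aliased by preceding terms (0 df)"
            logger.warning(msg)
            warnings_.append(msg)
        term_results.append(
            TermResult(
                term=term,
                df=dfs[k],
                ss=float(term_ss[k]) if not aliased else 0.0,
                r_squared=float(term_ss[k] / total_ss) if total_ss > 0 and not aliased else 0.0,
                pseudo_f=float(f_obs[k]),
                p_value=float(p_values[k]),
                scheme=schemes[k],
                aliased=aliased,
            )
        )
    return PermanovaResult(
        terms=term_results,
        residual_df=df_res,
        residual_ss=float(ss_res),
        residual_r_squared=float(ss_res / total_ss) if total_ss > 0 else 0.0,
        total_ss=total_ss,
        n_permutations="exact" if exact else n_perm,
        strata=strata,
        seed=seed,
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# Analysis suites
# ---------------------------------------------------------------------------

def run_variance_partition(
    normalized: AsvTable,
    meta: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "bray_curtis",
    include_clinical: bool = True,
) -> dict[str, PermanovaResult]:
    """The study's PERMANOVA suite.

    (i) pooled HC+NLS model with terms status, depth, time, participant
    (participant last so the earlier factors are not aliased by it);
    (ii) per-depth status models with participant strata;
    (iii) per-depth NLS models for O-SCORAD and filaggrin, and LS models for
    body location, all with participant strata. Samples are subset before
    distance computation.
    """
    m = meta.loc[~meta["is_negative_control"]].copy()
    m = m.loc[m["sample_id"].isin(normalized.sample_ids)]
    results: dict[str, PermanovaResult] = {}

    def run(name, subset, terms, strata):
        sids = subset["sample_id"].tolist()
        if len(sids) < 3:
            logger.warning("model %s skipped: fewer than 3 samples", name)
            return
        sub_table = normalized.subset_samples(sids)
        dm = compute_distance(sub_table, metric=metric)
        results[name] = permanova(
            dm, subset, terms, n_perm=n_perm, strata=strata, seed=seed
        )

    hc_nls = m.loc[m["skin_status"].isin(["HC", "NLS"])]
    run(
        "pooled_hc_nls", hc_nls,
        ["skin_status", "depth", "timepoint", "participant_id"], None,
    )
    for depth in ("surface", "within"):
        sub = hc_nls.loc[hc_nls["depth"] == depth]
        run(f"status_{depth}", sub, ["skin_status"], "participant_id")
    if include_clinical:
        nls = m.loc[m["skin_status"] == "NLS"]
        for depth in ("surface", "within"):
            sub = nls.loc[nls["depth"] == depth]
            if sub["oscorad"].notna().all() and len(sub) >= 3:
                run(f"oscorad_{depth}", sub, ["oscorad"], "participant_id")
            if sub["filaggrin_mutation"].notna().all() and len(sub) >= 3:
                sub2 = sub.copy()
                sub2["filaggrin_mutation"] = sub2["filaggrin_mutation"].astype(bool)
                run(f"filaggrin_{depth}", sub2, ["filaggrin_mutation"], "participant_id")
        ls = m.loc[m["skin_status"] == "LS"]
        for depth in ("surface", "within"):
            sub = ls.loc[ls["depth"] == depth]
            if len(sub) >= 3 and sub["body_location"].nunique() >= 2:
                run(f"location_{depth}", sub, ["body_location"], "participant_id")
    return results
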