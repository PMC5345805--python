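"""Directional selection test on gene expression across biochemical pathways.

Each measured gene carries a ternary direction value (+1 up, -1 down, 0
unchanged).  A pathway's score S is the sum of its genes' values; |S| is
large when expression changes point the same way across the pathway.  The
null distribution of S is built empirically: random gene sets of the same
size are drawn without replacement from the transcriptome *excluding the
pathway's own genes*, and their scores collected (100,000 draws by
default, or exhaustive enumeration when the number of subsets is small).
The one-sided empirical p-value is sign-conditional: for S > 0 it is the
fraction of null scores >= S ("up"), for S < 0 the fraction <= S ("down");
S = 0 carries no direction and gets p = 1.  Raw p-values are corrected by
multiplying with the number of pathways tested (Bonferroni, capped at 1).

Because a ternary draw is fully described by how many +1 and -1 genes it
contains, Monte-Carlo sampling uses the multivariate hypergeometric
distribution over the (+1, -1, 0) counts of the eligible universe — exactly
equivalent to drawing gene subsets uniformly without replacement, at a
fraction of the cost.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Pathway, PathwaySet

#: exhaustive enumeration is used (when requested) only below this many subsets
EXHAUSTIVE_CAP = 500_000

RESULT_COLUMNS = (
    "pathway_id", "n", "S", "p_raw", "p_corrected",
    "p_length_normalized", "direction", "n_perm",
)


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    n: int                      # pathway size after restriction to the universe
    S: int                      # directional score, |S| <= n
    p_raw: float                # one-sided sign-conditional empirical p
    p_corrected: float          # min(1, p_raw * number of pathways tested)
    p_length_normalized: float  # tail p of S/n against null/n
    direction: str              # "up" | "down" | "none"
    n_perm: int
    mean_score: float = 0.0     # S / n


@dataclass
class AnalysisConfig:
    """Knobs of the directionality analysis; defaults follow the study design."""

    seed: int = 0
    n_perm: int = 100_000
    fc_threshold: float = 1.5
    q_threshold: float = 0.05
    strict_fc: bool = False
    min_genes: int = 4
    excluded_categories: tuple[str, ...] = ()
    #: share one size-class null (no self-exclusion) instead of per-pathway nulls
    shared_size_class_null: bool = False
    #: add-one pseudocount so empirical p is never exactly 0
    pseudocount: bool = False
    exhaustive: bool = False


def filter_pathways(pathways: PathwaySet, universe: Iterable[str],
                    min_genes: int = 4,
                    excluded_categories: Iterable[str] = ()) -> PathwaySet:
    """Restrict pathways to measured genes and drop small/excluded ones.

    Each pathway is first intersected with the measured-gene universe;
    pathways whose restricted size falls below ``min_genes`` (default 4) are
    dropped, as are pathways whose category is in ``excluded_categories``
    (e.g. amino-acid and DNA biosynthesis sets, which share little with
    carbon metabolism but inflate the multiple-testing burden).
    """
    if not isinstance(universe, (set, frozenset)):
        universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    excluded = set(excluded_categories)
    kept: list[Pathway] = []
    for p in pathways:
        if p.category in excluded:
            continue
        restricted = p.genes & universe
        if len(restricted) < min_genes:
            continue
        kept.append(Pathway(p.pathway_id, frozenset(restricted), p.category))
    return PathwaySet(kept)


def pathway_score(directions: pd.Series, genes: Iterable[str]) -> int:
    """S = sum of ternary direction values over the pathway's genes."""
    genes = list(genes)
    missing = [g for g in genes if g not in directions.index]
    if missing:
        raise KeyError(
            f"{len(missing)} pathway gene(s) not in the measured universe "
            f"(restrict pathways first): {', '.join(sorted(missing)[:5])}"
        )
    return int(directions.loc[genes].sum())


def _pathway_rng(master_seed: int, pathway_id: str) -> np.random.Generator:
    # stream derived from (seed, pathway id): results do not depend on the
    # order in which pathways are processed
    digest = hashlib.sha256(pathway_id.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), sub]))


def null_distribution(directions: pd.Series, n: int,
                      exclude: Iterable[str] = (),
                      n_perm: int = 100_000,
                      rng: np.random.Generator | None = None,
                      exhaustive: bool = False,
                      exhaustive_cap: int = EXHAUSTIVE_CAP) -> np.ndarray:
    """Empirical null of pathway scores for size-n gene sets.

    Draws ``n_perm`` sets of ``n`` distinct genes uniformly without
    replacement from the universe minus ``exclude`` (the pathway's own
    genes) and returns their summed direction values.  With
    ``exhaustive=True`` and at most ``exhaustive_cap`` subsets, every
    C(|universe \\ exclude|, n) subset is enumerated instead, giving the
    exact null.
    """
    exclude = set(exclude)
    eligible = directions[~directions.index.isin(exclude)] if exclude else directions
    m = len(eligible)
    if n > m:
        raise ValueError(f"cannot draw {n} genes from {m} eligible")
    if n <= 0:
        raise ValueError("pathway size must be positive")
    values = eligible.to_numpy()
    if exhaustive:
        total = math.comb(m, n)
        if total > exhaustive_cap:
            raise ValueError(
                f"C({m},{n}) = {total} subsets exceeds the exhaustive cap "
                f"({exhaustive_cap}); use Monte-Carlo sampling"
            )
        return np.fromiter(
            (values[list(c)].sum() for c in combinations(range(m), n)),
            dtype=np.int64, count=total,
        )
    if rng is None:
        rng = np.random.default_rng()
    counts = [int((values == 1).sum()), int((values == -1).sum()),
              int((values == 0).sum())]
    draws = rng.multivariate_hypergeometric(counts, n, size=n_perm)
    return (draws[:, 0] - draws[:, 1]).astype(np.int64)


def empirical_pvalue(S: int, null: Sequence[int],
                     pseudocount: bool = False) -> tuple[float, str]:
    """Sign-conditional one-sided empirical p-value and direction.

    For S > 0: p = #{null >= S} / N, direction "up"; for S < 0:
    p = #{null <= S} / N, direction "down".  Tail counting is non-strict,
    so the observed tail is never empty on ties.  S = 0 defines no tail:
    p = 1, direction "none".  With ``pseudocount=True`` the count and the
    denominator each gain 1, keeping p strictly positive.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if S > 0:
        count, direction = int((null >= S).sum()), "up"
    elif S < 0:
        count, direction = int((null <= S).sum()), "down"
    else:
        return 1.0, "none"
    if pseudocount:
        return (count + 1) / (null.size + 1), direction
    return count / null.size, direction


def correct_pvalues(p_raw: Sequence[float], n_tested: int) -> np.ndarray:
    """Multiply by the number of pathways tested, capped at 1 (Bonferroni)."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_tested)


def length_normalized_pvalue(S: int, n: int, null: Sequence[int],
                             pseudocount: bool = False) -> tuple[float, float]:
    """Tail p of the length-averaged score S/n against null/n.

    Dividing score and null by the same positive n is order-preserving, so
    this must equal :func:`empirical_pvalue` exactly; the operation exists
    to assert that pathway length does not bias the test and to report the
    averaged score.  Returns (p, averaged score).
    """
    if n <= 0:
        raise ValueError("pathway size must be positive")
    null = np.asarray(null, dtype=float) / n
    s_avg = S / n
    if s_avg > 0:
        count = int((null >= s_avg).sum())
    elif s_avg < 0:
        count = int((null <= s_avg).sum())
    else:
        return 1.0, 0.0
    if pseudocount:
        return (count + 1) / (null.size + 1), s_avg
    return count / null.size, s_avg


def length_bias_check(results: Sequence[PathwayResult] | pd.DataFrame
                      ) -> tuple[float, float]:
    """Spearman rank correlation between raw p-values and pathway length.

    A significant correlation would indicate that pathway size, not
    expression direction, drives the p-values.  Returns (rho, two-sided p);
    both are NaN when either variable is constant.
    """
    if isinstance(results, pd.DataFrame):
        p, n = results["p_raw"].to_numpy(float), results["n"].to_numpy(float)
    else:
        p = np.array([r.p_raw for r in results], dtype=float)
        n = np.array([r.n for r in results], dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 pathway results for the bias check")
    if np.all(p == p[0]) or np.all(n == n[0]):
        return float("nan"), float("nan")
    rho, pval = stats.spearmanr(p, n)
    return float(rho), float(pval)


@dataclass
class DirectionalityRun:
    """Results table plus run metadata for one directionality analysis."""

    results: pd.DataFrame
    n_tested: int
    seed: int
    n_perm: int
    length_bias_rho: float
    length_bias_p: float
    n_up: int = 0
    n_down: int = 0

    def summary(self) -> dict:
        return {
            "pathways_tested": self.n_tested,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "length_bias_spearman_rho": self.length_bias_rho,
            "length_bias_spearman_p": self.length_bias_p,
            "genes_up": self.n_up,
            "genes_down": self.n_down,
        }


def directional_pathway_test(directions: pd.Series, pathways: PathwaySet,
                     config: AnalysisConfig) -> DirectionalityRun:
    """Score every pathway against its size-matched null and correct p-values.

    ``pathways`` must already be restricted/filtered against the direction
    map's universe (see :func:`filter_pathways`).
    """
    rows = []
    nulls_by_size: dict[int, np.ndarray] = {}
    for p in pathways:
        n = len(p.genes)
        S = pathway_score(directions, p.genes)
        if config.shared_size_class_null:
            if n not in nulls_by_size:
                rng = _pathway_rng(config.seed, f"size-class-{n}")
                nulls_by_size[n] = null_distribution(
                    directions, n, exclude=(), n_perm=config.n_perm,
                    rng=rng, exhaustive=config.exhaustive)
            null = nulls_by_size[n]
        else:
            rng = _pathway_rng(config.seed, p.pathway_id)
            null = null_distribution(
                directions, n, exclude=p.genes, n_perm=config.n_perm,
                rng=rng, exhaustive=config.exhaustive)
        p_raw, direction = empirical_pvalue(S, null, config.pseudocount)
        p_len, s_avg = length_normalized_pvalue(S, n, null, config.pseudocount)
        rows.append((p.pathway_id, n, S, p_raw, p_len, direction, len(null), s_avg))
    n_tested = len(rows)
    df = pd.DataFrame(rows, columns=["pathway_id", "n", "S", "p_raw",
                                     "p_length_normalized", "direction",
                                     "n_perm", "mean_score"])
    df["p_corrected"] = correct_pvalues(df["p_raw"], n_tested) if n_tested else []
    df = df[list(RESULT_COLUMNS) + ["mean_score"]]
    if n_tested >= 3:
        rho, pbias = length_bias_check(df)
    else:
        rho, pbias = float("nan"), float("nan")
    return DirectionalityRun(
        results=df, n_tested=n_tested, seed=config.seed, n_perm=config.n_perm,
        length_bias_rho=rho, length_bias_p=pbias,
        n_up=int((directions == 1).sum()), n_down=int((directions == -1).sum()),
    )


def run_directionality_analysis(de_tables, pathways: PathwaySet,
                                config: AnalysisConfig | None = None
                                ) -> DirectionalityRun:
    """Full pipeline: misregulation calling, filtering, per-pathway testing.

    ``de_tables`` is a single DE table or a sequence of replicate tables
    (averaged first).  Returns the per-pathway results plus run metadata.
    """
    from .misregulation import average_replicate_fold_changes, call_misregulated

    if config is None:
        config = AnalysisConfig()
    if isinstance(de_tables, pd.DataFrame):
        table = de_tables
    else:
        table = average_replicate_fold_changes(list(de_tables))
    directions = call_misregulated(
        table, fc_threshold=config.fc_threshold,
        q_threshold=config.q_threshold, strict=config.strict_fc)
    tested = filter_pathways(pathways, set(directions.index),
                             min_genes=config.min_genes,
                             excluded_categories=config.excluded_categories)
    return directional_pathway_test(directions, tested, config)
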