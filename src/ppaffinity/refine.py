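"""Weight refinement and evaluation.

The category weights of the affinity model are fitted by a greedy
Monte-Carlo search that maximises the Pearson correlation between
calculated and experimental binding free energies: at each step one of
the 1950 weights is picked uniformly at random, a fresh uniform value in
[-1, 1] is proposed, and the move is accepted only if the correlation
strictly increases. The balance factor w_n is held fixed during a
refinement and explored only by the external scan.

Cross-validation is grouped: each run holds out one wild-type complex
together with all of its mutants, refines on the remaining families and
predicts the held-out family. Raw model-scale predictions are mapped
onto experimental units by moment matching against the refinement set
(mean and standard deviation of its experimental affinities).

The module also provides the downstream evaluation statistics: binary
mutation-effect classification metrics, a permutation test for the
significance of a correlation, the w_n scan, and region-stratified
correlations for single mutants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .dataset import AffinityDataset, design_matrices
from .errors import DegenerateDataError, PPAffinityError
from .model import (
    N_INTERFACIAL_CATEGORIES,
    N_NONINTERFACIAL_CATEGORIES,
    N_WEIGHTS,
    WeightVector,
)

__all__ = [
    "pearson",
    "MCConfig",
    "MCResult",
    "mc_refine",
    "adjust_predictions",
    "CVRun",
    "CVResult",
    "run_loocv",
    "mutation_effect_metrics",
    "permutation_test",
    "wn_scan",
    "region_stratified_pcc",
]


def pearson(calc: Sequence[float], exp: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Raises :class:`DegenerateDataError` for sequences shorter than two
    or with zero variance.
    """
    x = np.asarray(calc, dtype=float)
    y = np.asarray(exp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    if len(x) < 2:
        raise DegenerateDataError("need at least two points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise DegenerateDataError("zero variance in input sequence")
    return float(xc @ yc) / denom


@dataclass(frozen=True)
class MCConfig:
    """Settings of one greedy Monte-Carlo refinement."""

    seed: int = 0
    max_steps: int = 200_000
    stall_window: int = 20_000
    w_n: float = 0.7
    restarts: int = 1  # independent refinements averaged per CV run
    resync_every: int = 1_000  # full prediction recompute every N accepted moves
    validate_incremental: bool = False

    def __post_init__(self) -> None:
        if self.max_steps < 1 or self.stall_window < 1:
            raise ValueError("max_steps and stall_window must be >= 1")
        if not (0.0 <= self.w_n <= 1.0):
            raise ValueError("w_n must lie in [0, 1]")


@dataclass
class MCResult:
    """Outcome of one refinement: fitted weights and the accepted trace."""

    weights: WeightVector
    trace: np.ndarray  # objective after init and after every accepted move
    n_steps: int
    n_accepted: int
    max_incremental_error: float = 0.0

    @property
    def rho(self) -> float:
        return float(self.trace[-1])


def _effective_columns(
    x_itf: sparse.csr_matrix, x_nitf: sparse.csr_matrix, w_n: float, exp: np.ndarray
):
    """Per-parameter sparse columns of the w_n-scaled design matrix."""
    rows_of, vals_of, evals_of = [], [], []
    for block, scale in ((x_itf, 1.0), (x_nitf, w_n)):
        csc = block.tocsc()
        for k in range(csc.shape[1]):
            start, end = csc.indptr[k], csc.indptr[k + 1]
            rows = csc.indices[start:end].astype(np.intp)
            vals = csc.data[start:end] * scale
            rows_of.append(rows)
            vals_of.append(vals)
            evals_of.append(exp[rows])
    return rows_of, vals_of, evals_of


def mc_refine(
    dataset: AffinityDataset,
    config: MCConfig,
    init: WeightVector | None = None,
    rng: np.random.Generator | None = None,
) -> MCResult:
    """Greedy Monte-Carlo maximisation of the calculated/experimental
    correlation over the 1950 category weights.

    Starts from ``init`` (or uniform random weights in [-1, 1] under the
    config seed), proposes single-parameter replacements, accepts only
    strict improvements, and stops at ``max_steps`` or after
    ``stall_window`` consecutive rejections. The correlation is updated
    incrementally from running sums; predictions are periodically
    resynchronised by a full recompute.
    """
    exp = dataset.dg_exp
    n = len(exp)
    if n < 2:
        raise DegenerateDataError("need at least two records to refine")
    if np.ptp(exp) == 0.0:
        raise DegenerateDataError("all experimental affinities are equal")

    if rng is None:
        rng = np.random.default_rng(config.seed)
    x_itf, x_nitf = design_matrices(dataset.records)
    if init is None:
        weights = WeightVector.random(rng, w_n=config.w_n)
    else:
        weights = WeightVector(init.w_itf.copy(), init.w_nitf.copy(), config.w_n)
    w = weights.as_flat()

    rows_of, vals_of, evals_of = _effective_columns(x_itf, x_nitf, config.w_n, exp)

    def full_predictions(wvec: np.ndarray) -> np.ndarray:
        return x_itf @ wvec[:N_INTERFACIAL_CATEGORIES] + config.w_n * (
            x_nitf @ wvec[N_INTERFACIAL_CATEGORIES:]
        )

    se = float(exp.sum())
    see = float(exp @ exp)
    var_e = n * see - se * se
    if var_e <= 0:
        raise DegenerateDataError("zero variance in experimental affinities")

    p = full_predictions(w)
    sp = float(p.sum())
    spp = float(p @ p)
    spe = float(p @ exp)

    def rho_of(sp_, spp_, spe_) -> float:
        var_p = n * spp_ - sp_ * sp_
        if var_p <= 0:
            return -2.0  # degenerate predictions rank below any correlation
        return (n * spe_ - sp_ * se) / math.sqrt(var_p * var_e)

    rho = rho_of(sp, spp, spe)
    trace = [rho]
    n_accepted = 0
    rejections = 0
    max_err = 0.0

    ks = rng.integers(0, N_WEIGHTS, size=config.max_steps)
    proposals = rng.uniform(-1.0, 1.0, size=config.max_steps)

    step = 0
    for step in range(1, config.max_steps + 1):
        k = int(ks[step - 1])
        new = float(proposals[step - 1])
        rows = rows_of[k]
        if rows.size == 0:
            rejections += 1  # the move cannot change any prediction: a tie
            if rejections >= config.stall_window:
                break
            continue
        dw = new - w[k]
        vals = vals_of[k]
        dp = dw * vals
        pr = p[rows]
        d_sp = float(dp.sum())
        d_spe = float(dp @ evals_of[k])
        d_spp = float(2.0 * (pr @ dp) + dp @ dp)
        rho_new = rho_of(sp + d_sp, spp + d_spp, spe + d_spe)
        # the 1e-13 guard keeps sub-roundoff "improvements" from being
        # accepted and later reversed by the exact resynchronisation
        if rho_new > rho + 1e-13:
            w[k] = new
            p[rows] = pr + dp
            sp += d_sp
            spp += d_spp
            spe += d_spe
            rho = rho_new
            n_accepted += 1
            rejections = 0
            if config.validate_incremental or n_accepted % config.resync_every == 0:
                p = full_predictions(w)
                sp = float(p.sum())
                spp = float(p @ p)
                spe = float(p @ exp)
                exact = rho_of(sp, spp, spe)
                max_err = max(max_err, abs(exact - rho))
                rho = exact
            trace.append(rho)
        else:
            rejections += 1
            if rejections >= config.stall_window:
                break

    fitted = WeightVector(
        w[:N_INTERFACIAL_CATEGORIES], w[N_INTERFACIAL_CATEGORIES:], config.w_n
    )
    return MCResult(fitted, np.asarray(trace), step, n_accepted, max_err)


def adjust_predictions(
    test_preds: Sequence[float],
    refinement_calc: Sequence[float],
    refinement_exp: Sequence[float],
) -> np.ndarray:
    """Map raw model-scale predictions onto experimental units.

    Affine moment matching against the refinement set:

        adjusted_i = mean(exp) + (pred_i - mean(calc)) * sd(exp) / sd(calc)
    """
    preds = np.asarray(test_preds, dtype=float)
    calc = np.asarray(refinement_calc, dtype=float)
    exp = np.asarray(refinement_exp, dtype=float)
    sd_calc = float(calc.std())
    sd_exp = float(exp.std())
    if sd_calc == 0.0 or sd_exp == 0.0:
        raise DegenerateDataError("zero standard deviation in refinement sequences")
    return exp.mean() + (preds - calc.mean()) * sd_exp / sd_calc


def _predict_matrix(
    records, weights: WeightVector
) -> np.ndarray:
    x_itf, x_nitf = design_matrices(records)
    return x_itf @ weights.w_itf + weights.w_n * (x_nitf @ weights.w_nitf)


@dataclass
class CVRun:
    """One leave-one-family-out run."""

    family_id: str
    refinement_rho: float
    weights: WeightVector
    test_indices: list[int]
    test_pred_raw: np.ndarray
    test_pred_adjusted: np.ndarray
    train_family_ids: frozenset[str] = frozenset()


@dataclass
class CVResult:
    """Pooled outcome of grouped leave-one-out cross-validation."""

    runs: list[CVRun]
    predictions_raw: np.ndarray       # per dataset record, model units
    predictions_adjusted: np.ndarray  # per dataset record, kcal/mol
    pooled_rho: float
    repeat_rhos: list[float] = field(default_factory=list)

    @property
    def mean_refinement_rho(self) -> float:
        return float(np.mean([r.refinement_rho for r in self.runs]))


def _single_loocv(
    dataset: AffinityDataset, config: MCConfig, seed_seq: np.random.SeedSequence
) -> CVResult:
    families = dataset.families
    family_ids = dataset.family_ids
    if len(family_ids) < 2:
        raise DegenerateDataError("cross-validation needs at least two families")

    n = len(dataset)
    pred_raw = np.full(n, np.nan)
    pred_adj = np.full(n, np.nan)
    runs: list[CVRun] = []
    child_seeds = seed_seq.spawn(len(family_ids))

    for family_id, child in zip(family_ids, child_seeds):
        test_idx = families[family_id]
        train_idx = [i for i in range(n) if dataset.records[i].family_id != family_id]
        train = dataset.subset(train_idx)

        # Categories absent from the refinement set are never moved by the
        # greedy search (every proposal on them is a tie), so their final
        # values are bare initial noise; they contribute zero at prediction
        # time. Independent restarts are averaged to suppress the remaining
        # initialisation noise in weakly constrained directions.
        x1_train, x2_train = design_matrices(train.records)
        seen = np.concatenate([
            np.asarray(x1_train.getnnz(axis=0) > 0).ravel(),
            np.asarray(x2_train.getnnz(axis=0) > 0).ravel(),
        ])
        flat_sum = np.zeros(N_WEIGHTS)
        rhos = []
        for restart_seed in child.spawn(max(1, config.restarts)):
            result = mc_refine(train, config, rng=np.random.default_rng(restart_seed))
            flat_sum += np.where(seen, result.weights.as_flat(), 0.0)
            rhos.append(result.rho)
        flat = flat_sum / max(1, config.restarts)
        weights = WeightVector(
            flat[:N_INTERFACIAL_CATEGORIES], flat[N_INTERFACIAL_CATEGORIES:], config.w_n
        )

        train_calc = _predict_matrix(train.records, weights)
        test_records = [dataset.records[i] for i in test_idx]
        raw = _predict_matrix(test_records, weights)
        adjusted = adjust_predictions(raw, train_calc, train.dg_exp)

        pred_raw[test_idx] = raw
        pred_adj[test_idx] = adjusted
        runs.append(
            CVRun(family_id, float(np.mean(rhos)), weights, list(test_idx), raw,
                  adjusted, frozenset(r.family_id for r in train.records))
        )

    pooled = pearson(pred_adj, dataset.dg_exp)
    return CVResult(runs, pred_raw, pred_adj, pooled)


def run_loocv(
    dataset: AffinityDataset, config: MCConfig, repeats: int = 1
) -> CVResult:
    """Grouped leave-one-out cross-validation.

    One run per family: the held-out family (wild type plus all mutants)
    is predicted with weights refined on every other family, and its raw
    predictions are adjusted to the refinement set's experimental
    moments. The pooled testing correlation is computed over all records
    after all runs.

    With ``repeats > 1`` the whole procedure is repeated with independent
    seed streams; the returned result is the first repeat with the pooled
    correlations of every repeat in ``repeat_rhos``.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(repeats)
    results = [_single_loocv(dataset, config, child) for child in children]
    first = results[0]
    first.repeat_rhos = [r.pooled_rho for r in results]
    return first


def mutation_effect_metrics(
    dataset: AffinityDataset, predictions: Sequence[float]
) -> dict[str, float]:
    """Binary classification of mutation effects on binding.

    A mutation *increases* binding affinity when binding becomes stronger
    (its ΔG drops below the wild type's). Directions are compared between
    experiment and prediction per mutant; exactly-zero differences count
    as "decrease". Returns sensitivity, specificity, precision, accuracy
    and the raw confusion counts.
    """
    preds = np.asarray(predictions, dtype=float)
    if len(preds) != len(dataset):
        raise ValueError("one prediction per dataset record required")
    tp = fn = tn = fp = 0
    for family_id, indices in dataset.families.items():
        wt_idx = dataset.wildtype_index(family_id)
        if not np.isfinite(preds[wt_idx]):
            raise PPAffinityError(f"family {family_id!r} lacks a wild-type prediction")
        for i in indices:
            if i == wt_idx:
                continue
            if not np.isfinite(preds[i]):
                raise PPAffinityError(f"record {dataset.records[i].complex_id!r} lacks a prediction")
            exp_increase = (dataset.records[i].dg_exp - dataset.records[wt_idx].dg_exp) < 0
            pred_increase = (preds[i] - preds[wt_idx]) < 0
            if exp_increase and pred_increase:
                tp += 1
            elif exp_increase:
                fn += 1
            elif pred_increase:
                fp += 1
            else:
                tn += 1

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "accuracy": ratio(tp + tn, tp + fn + tn + fp),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


def permutation_test(
    calc: Sequence[float],
    exp: Sequence[float],
    n_perm: int = 1_000_000,
    seed: int = 0,
) -> float:
    """One-sided permutation p-value for a Pearson correlation.

    The experimental values stay fixed while the calculated values are
    reshuffled uniformly at random ``n_perm`` times; p is the fraction of
    permuted correlations at least as large as the observed one, with a
    resolution floor of 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(calc, dtype=float)
    y = np.asarray(exp, dtype=float)
    observed = pearson(x, y)

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    count = 0
    chunk = max(1, min(n_perm, 200_000 // max(1, len(x)) + 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, len(x))), axis=1)
        rhos = (xc[perms] @ yc) / (sx * sy)
        # tolerance guards the observed correlation's own rounding when the
        # identity permutation is drawn
        count += int(np.sum(rhos >= observed - 1e-12))
        done += m
    return max(count, 0) / n_perm if count > 0 else 1.0 / n_perm


def wn_scan(
    dataset: AffinityDataset,
    w_values: Sequence[float],
    config: MCConfig,
    repeats: int = 1,
) -> list[dict[str, float]]:
    """Run the full cross-validation at each w_n value.

    Returns one row per w_n with the mean refinement correlation and the
    pooled testing correlation — the scan that locates the optimal
    balance between interfacial and non-interfacial contributions.
    """
    rows = []
    for w_n in w_values:
        if not (0.0 <= w_n <= 1.0):
            raise ValueError("w_n values must lie in [0, 1]")
        cv = run_loocv(dataset, dataclasses.replace(config, w_n=float(w_n)), repeats=repeats)
        rows.append(
            {
                "w_n": float(w_n),
                "refinement_rho": cv.mean_refinement_rho,
                "testing_rho": cv.pooled_rho,
            }
        )
    return rows


def region_stratified_pcc(
    dataset: AffinityDataset,
    predictions: Sequence[float],
    min_records: int = 3,
) -> dict[str, float | None]:
    """Pearson correlation per structural region over single mutants.

    Each single-mutant record is grouped by the five-region label of its
    mutated site in the wild-type structure; regions with fewer than
    ``min_records`` single mutants are reported as ``None``.
    """
    preds = np.asarray(predictions, dtype=float)
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        if len(rec.mutations) == 1 and rec.mutation_region is not None:
            groups.setdefault(rec.mutation_region, []).append(i)
    out: dict[str, float | None] = {}
    for region, indices in sorted(groups.items()):
        if len(indices) < min_records:
            out[region] = None
            continue
        out[region] = pearson(preds[indices], dataset.dg_exp[indices])
    return out
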