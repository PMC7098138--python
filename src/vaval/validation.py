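"""Repeated train/test validation harness with Dirichlet-recomposed test sets.

Each split stratifies the labelled dataset into train and test partitions
by cause, draws a target cause composition from a Dirichlet(alpha)
distribution, and rebuilds the test set by resampling (with replacement)
from the raw test partition to match that composition.  Varying the test
composition across splits is what makes the population-level metrics
informative: an estimator that merely reproduces the training CSMF is
penalized when the test composition differs from it.

For each split the harness extracts a conditional-probability matrix from
the training partition only, runs the Bayesian sampler on the recomposed
test set, assigns top causes, and computes the split's metrics — once with
all symptoms and once with the health-care-experience (HCE) block removed,
when both arms are requested.  Split-level results are summarized as the
median and 95% uncertainty interval across splits.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .insilico import InsilicoConfig, insilico_fit, top_cause
from .metrics import MetricResult, MetricSummary, compute_metrics, summarize_splits
from .probbase import LevelTable, ProbMode, bin_to_levels, extract_prob_raw
from .symptoms import SymptomMatrix, strip_hce

HCE_CONDITIONS = ("hce", "no_hce")


@dataclass
class ValidationDesign:
    """Parameters of the repeated-split validation design.

    hce is one of "with", "without", "both".  test_size defaults to the raw
    test-partition size of each split.  All per-split randomness derives
    from ``seed``.
    """

    n_splits: int = 500
    train_fraction: float = 0.75
    dirichlet_alpha: float = 1.0
    test_size: Optional[int] = None
    hce: str = "both"
    seed: int = 0
    probbase_mode: ProbMode = ProbMode.RAW
    level_table: Optional[LevelTable] = None
    sampler_config: InsilicoConfig = field(default_factory=InsilicoConfig)

    def __post_init__(self):
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.hce not in ("with", "without", "both"):
            raise ValueError("hce must be 'with', 'without' or 'both'")
        self.probbase_mode = ProbMode(self.probbase_mode)

    @property
    def conditions(self) -> tuple:
        if self.hce == "with":
            return ("hce",)
        if self.hce == "without":
            return ("no_hce",)
        return HCE_CONDITIONS


@dataclass
class SplitResult:
    """Per-split record: one MetricResult per requested HCE condition."""

    split_index: int
    metrics: dict               # condition -> MetricResult
    acceptance_rates: dict      # condition -> float
    convergence_warnings: dict  # condition -> bool

    def as_dict(self) -> dict:
        return {
            "split_index": self.split_index,
            "metrics": {c: m.as_dict() for c, m in self.metrics.items()},
            "acceptance_rates": self.acceptance_rates,
            "convergence_warnings": self.convergence_warnings,
        }


def _split_seed(master: int, split_index: int, condition: str = "") -> int:
    """Deterministic per-(split, condition) seed below 2**31."""
    tag = sum(ord(ch) for ch in condition)
    ss = np.random.SeedSequence([int(master), int(split_index), tag])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` counts to match the target fractions exactly.

    Floor each share, then hand remaining units to the largest fractional
    remainders (ties to the lowest index).  Deterministic; sums to total.
    """
    target = np.asarray(target, dtype=float)
    raw = target * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        remainders = raw - counts
        order = np.lexsort((np.arange(target.size), -remainders))
        counts[order[:short]] += 1
    return counts


def make_split(dataset: SymptomMatrix, design: ValidationDesign,
               split_index: int):
    """One stratified split with a Dirichlet-recomposed test set.

    Returns (train, test, true_test_csmf): the recomposed test set is drawn
    with replacement from the raw test partition to match a target CSMF
    drawn from Dirichlet(alpha); ``true_test_csmf`` is the exact empirical
    CSMF of the recomposed set.  Deterministic given (seed, split_index).
    """
    if dataset.causes is None:
        raise ValueError("validation needs gold-standard cause labels")
    cause_dict = dataset.cause_dict
    if cause_dict is None:
        raise ValueError("validation needs a cause dictionary on the dataset")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(design.seed), int(split_index)]))
    C = len(cause_dict)

    train_idx, test_pools = [], {}
    for code in cause_dict.codes:
        idx = np.flatnonzero(dataset.causes == code)
        if idx.size < 2:
            raise ValueError(
                f"cause {code!r} has {idx.size} deaths; need at least 2")
        idx = rng.permutation(idx)
        n_train = int(round(design.train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_pools[code] = idx[n_train:]
    train_idx = np.sort(np.concatenate(train_idx))

    raw_test_size = sum(len(v) for v in test_pools.values())
    test_size = design.test_size or raw_test_size
    target = rng.dirichlet(np.full(C, design.dirichlet_alpha))
    counts = largest_remainder(target, test_size)

    test_idx = []
    for code, count in zip(cause_dict.codes, counts):
        if count == 0:
            continue
        pool = test_pools[code]
        test_idx.append(rng.choice(pool, size=count, replace=True))
    test_idx = np.concatenate(test_idx) if test_idx else np.empty(0, dtype=int)

    train = dataset.take_deaths(train_idx)
    test = dataset.take_deaths(test_idx)
    true_test_csmf = counts / counts.sum()
    return train, test, true_test_csmf


def _evaluate_condition(train, test, true_test_csmf, design, seed):
    """Probbase from train only; sampler on the test set; metrics."""
    probbase = extract_prob_raw(train, cause_dict=train.cause_dict)
    if design.probbase_mode is not ProbMode.RAW:
        probbase = bin_to_levels(probbase, levels=design.level_table,
                                 mode=design.probbase_mode)
    config = replace(design.sampler_config, seed=seed)
    draws = insilico_fit(test, probbase, config)
    assigned = np.asarray(
        [top_cause(p, draws.cause_codes) for p in draws.individual_probs])
    result = compute_metrics(assigned, test.causes, true_test_csmf,
                             draws.csmf_mean, train.cause_dict)
    warning = bool(draws.diagnostics.get("warning", False))
    return result, draws.acceptance_rate, warning


def run_split(dataset: SymptomMatrix, design: ValidationDesign,
              split_index: int) -> SplitResult:
    """Full evaluation of one split across the requested HCE conditions."""
    train, test, true_csmf = make_split(dataset, design, split_index)
    metrics, rates, warns = {}, {}, {}
    for cond in design.conditions:
        if cond == "no_hce":
            tr, te = strip_hce(train), strip_hce(test)
        else:
            tr, te = train, test
        seed = _split_seed(design.seed, split_index, cond)
        try:
            m, rate, warn = _evaluate_condition(tr, te, true_csmf, design, seed)
        except Exception as exc:
            raise RuntimeError(
                f"split {split_index}, condition {cond!r}: {exc}") from exc
        metrics[cond], rates[cond], warns[cond] = m, rate, warn
    return SplitResult(split_index=split_index, metrics=metrics,
                       acceptance_rates=rates, convergence_warnings=warns)


def _load_log(log_path: pathlib.Path) -> dict:
    done = {}
    if log_path.exists():
        with open(log_path) as fh:
            for line in fh:
                rec = json.loads(line)
                done[rec["split_index"]] = rec
    return done


def _result_from_record(rec: dict) -> SplitResult:
    metrics = {c: MetricResult(**m) for c, m in rec["metrics"].items()}
    return SplitResult(split_index=rec["split_index"], metrics=metrics,
                       acceptance_rates=rec["acceptance_rates"],
                       convergence_warnings=rec["convergence_warnings"])


def run_validation(dataset: SymptomMatrix, design: ValidationDesign,
                   out_dir=None):
    """Run all splits and summarize into the four-row metric table.

    When ``out_dir`` is given, per-split results are appended to
    ``splits.jsonl`` as they complete and already-logged splits are not
    recomputed, so an interrupted run resumes where it stopped.

    Returns (summary_table, split_results): the table is a DataFrame with
    rows CCCSMFA/CCC x no-HCE/HCE (for the requested conditions) and
    columns median / ui_low / ui_high.
    """
    log_path = None
    done = {}
    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "splits.jsonl"
        done = _load_log(log_path)

    results = []
    for i in range(design.n_splits):
        if i in done:
            results.append(_result_from_record(done[i]))
            continue
        res = run_split(dataset, design, i)
        results.append(res)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(res.as_dict()) + "\n")

    table = summary_table(results, design.conditions)
    if out_dir is not None:
        table.to_csv(out_dir / "summary.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(table.to_dict(orient="index"), fh, indent=2)
    return table, results


_ROW_LABELS = {("cccsmfa", "no_hce"): "CCCSMFA: no HCE",
               ("cccsmfa", "hce"): "CCCSMFA: HCE",
               ("ccc_mean", "no_hce"): "CCC: no HCE",
               ("ccc_mean", "hce"): "CCC: HCE"}


def summary_table(results, conditions=HCE_CONDITIONS) -> pd.DataFrame:
    """Median (95% UI) table across splits, one row per metric x condition."""
    rows = {}
    for cond in conditions:
        summary = summarize_splits([r.metrics[cond] for r in results])
        for metric in ("cccsmfa", "ccc_mean"):
            label = _ROW_LABELS[(metric, cond)]
            rows[label] = {
                "median": summary.median[metric],
                "ui_low": summary.ui_low[metric],
                "ui_high": summary.ui_high[metric],
            }
    order = [label for key, label in _ROW_LABELS.items() if label in rows]
    return pd.DataFrame.from_dict(rows, orient="index").loc[order]
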