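"""Training protocol, seed ensembling, evaluation, and experiment drivers.

The protocol mirrors common practice for personalized physiological models:
a generic model is pre-trained on the pooled training data of all subjects,
then fine-tuned per subject by continuing optimization on that subject's
training split alone.  Early stopping watches the validation loss with a
patience of 10 epochs and restores the best-validation-epoch weights.  Runs
are repeated over 10 seeds; reported scores are either the mean over seeds
or the score of the seed with the best *validation* MAE (test data is never
consulted for selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Adam
from .baselines import fit_global, fit_tod, unique_events
from .example_builder import TAU_GRID, build_examples
from .preprocessing import Scaler, anchor_meals, fit_scaler, interpolate_glucose
from .recommender_models import (
    LSTMChain, ResidualStack, default_chain_config, default_stack_config,
    encode_example, training_loss,
)
from .timeseries_core import SubjectRecord, ValidationError, assign_split, to_grid

logger = logging.getLogger("bolusrec")


@dataclass
class TrainProtocol:
    learning_rate: float = 0.001
    batch_size: int = 64
    patience: int = 10            # early-stopping inertia, epochs
    max_epochs: int = 500
    seeds: tuple = tuple(range(1, 11))
    alpha: float = 1.0            # per-block forecast loss weight
    beta: float = 1.0             # per-block backcast loss weight

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def early_stop_epoch(val_losses, patience: int = 10) -> int:
    """Number of epochs run before early stopping halts training: exactly
    ``patience`` epochs after the last (strict) validation improvement."""
    best = np.inf
    best_i = -1
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_i = v, i
        elif i - best_i >= patience:
            return i + 1
    return len(val_losses)


# ---------------------------------------------------------------------------
# Per-subject data preparation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: str
    scaler: Scaler
    train: list
    val: list
    test: list
    record: SubjectRecord = None


def prepare_subject(record: SubjectRecord, scenario: str,
                    example_class: str = "inertial", anchor: bool = True,
                    match_window: int = 60, test_days: int = 10,
                    val_days: int = 10) -> SubjectData:
    """Run the full per-subject pipeline: anchoring (optional, for the raw-data
    ablation), gap interpolation, chronological split, example building, and
    scaler fitting on the training portion only."""
    rec = anchor_meals(record, match_window=match_window) if anchor else record
    rec = interpolate_glucose(rec)
    assign_split(rec, test_days=test_days, val_days=val_days)
    examples = build_examples(rec, scenario, example_class,
                              require_anchored=anchor)
    train_end, val_end = rec.split
    ev_time = lambda ex: ex.t + 10
    train = [ex for ex in examples if ev_time(ex) < train_end]
    val = [ex for ex in examples if train_end <= ev_time(ex) < val_end]
    test = [ex for ex in examples if ev_time(ex) >= val_end]
    if not train:
        raise ValidationError(
            f"subject {rec.subject_id}: no training examples for {scenario}")
    # scaler on training-portion grid + training labels
    grid = to_grid(rec)
    k_end = int(train_end) // 5
    from .timeseries_core import GriddedSeries
    train_grid = GriddedSeries(bg=grid.bg[:k_end], carbs=grid.carbs[:k_end],
                               bolus=grid.bolus[:k_end], basal=grid.basal[:k_end],
                               interpolated=grid.interpolated[:k_end])
    scaler = fit_scaler(train_grid, [ex.label for ex in train])
    return SubjectData(subject_id=rec.subject_id, scaler=scaler,
                       train=train, val=val, test=test, record=rec)


# ---------------------------------------------------------------------------
# Batching (windows are tau-dependent, so batches are tau-homogeneous)
# ---------------------------------------------------------------------------

def _group_encode(examples, scaler: Scaler) -> dict:
    groups = {}
    for idx, ex in enumerate(examples):
        enc = encode_example(ex, scaler)
        groups.setdefault(ex.tau, []).append((idx, enc))
    out = {}
    for tau, items in groups.items():
        idxs = np.array([i for i, _ in items])
        out[tau] = {
            "idx": idxs,
            "hist": np.stack([e.history for _, e in items]),
            "win": np.stack([e.window for _, e in items]),
            "extras": np.stack([e.extras for _, e in items]),
            "label": np.array([e.label for _, e in items]),
        }
    return out


def _epoch_batches(groups: dict, batch_size: int, rng: np.random.Generator):
    plan = []
    for tau in sorted(groups):
        g = groups[tau]
        n = len(g["label"])
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            plan.append((tau, order[s:s + batch_size]))
    rng.shuffle(plan)
    for tau, sel in plan:
        g = groups[tau]
        yield g["hist"][sel], g["win"][sel], g["extras"][sel], g["label"][sel]


def _forward(model, hist, win, extras, train=False, drop_rng=None):
    out = model.forward(hist, win, extras, train=train, drop_rng=drop_rng)
    if isinstance(out, tuple):
        return out
    return out, None


def dataset_loss(model, groups: dict, alpha: float = 1.0, beta: float = 1.0) -> float:
    """Example-weighted mean training loss over a whole (encoded) dataset."""
    total, n = 0.0, 0
    for tau in sorted(groups):
        g = groups[tau]
        est, blocks = _forward(model, g["hist"], g["win"], g["extras"])
        loss = training_loss(est, blocks, g["label"], alpha, beta)
        total += float(loss.data) * len(g["label"])
        n += len(g["label"])
    return total / max(n, 1)


def train_model(model, train_groups: dict, val_groups: dict,
                protocol: TrainProtocol, seed: int = 1):
    """Adam + early stopping; restores the best-validation-epoch weights.

    Returns ``(model, history)`` where history is the per-epoch validation
    loss list.  Deterministic for a fixed seed and platform.
    """
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng((seed * 2654435761) % (2 ** 31))
    opt = Adam(model.params, lr=protocol.learning_rate)
    best = np.inf
    best_epoch = -1
    best_params = {k: p.data.copy() for k, p in model.params.items()}
    history = []
    for epoch in range(protocol.max_epochs):
        for hist, win, extras, label in _epoch_batches(
                train_groups, protocol.batch_size, rng):
            opt.zero_grad()
            est, blocks = _forward(model, hist, win, extras, train=True,
                                   drop_rng=drop_rng)
            loss = training_loss(est, blocks, label, protocol.alpha, protocol.beta)
            loss.backward()
            opt.step()
        vl = dataset_loss(model, val_groups, protocol.alpha, protocol.beta) \
            if val_groups else dataset_loss(model, train_groups,
                                            protocol.alpha, protocol.beta)
        history.append(vl)
        if vl < best:
            best, best_epoch = vl, epoch
            best_params = {k: p.data.copy() for k, p in model.params.items()}
        elif epoch - best_epoch >= protocol.patience:
            break
    for k, p in model.params.items():
        p.data = best_params[k]
    return model, history


def model_factory(scenario: str, example_class: str, model_kind: str,
                  seed: int = 0, config=None):
    if model_kind == "lstm":
        cfg = config or default_chain_config(scenario, example_class)
        return LSTMChain(cfg, seed=seed)
    if model_kind in ("nbeats", "stack"):
        cfg = config or default_stack_config(scenario, example_class)
        return ResidualStack(cfg, seed=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def pretrain_global(subjects: list[SubjectData], scenario: str,
                    example_class: str, model_kind: str,
                    protocol: TrainProtocol, seed: int = 1, config=None):
    """Train one generic model on the pooled (per-subject-scaled) training
    examples of all subjects, early-stopped on the pooled validation loss."""
    train_groups, val_groups = {}, {}
    for sub in subjects:
        for target, examples in ((train_groups, sub.train), (val_groups, sub.val)):
            for tau, g in _group_encode(examples, sub.scaler).items():
                if tau in target:
                    t = target[tau]
                    for k in ("hist", "win", "extras"):
                        t[k] = np.concatenate([t[k], g[k]])
                    t["label"] = np.concatenate([t["label"], g["label"]])
                    t["idx"] = np.concatenate([t["idx"], g["idx"]])
                else:
                    target[tau] = dict(g)
    if not train_groups:
        raise ValidationError("no pooled training examples")
    model = model_factory(scenario, example_class, model_kind, seed=seed,
                          config=config)
    model, history = train_model(model, train_groups, val_groups, protocol,
                                 seed=seed)
    return model, history


def finetune_subject(model, subject: SubjectData, protocol: TrainProtocol,
                     seed: int = 1):
    """Continue training from the given (pre-trained) parameters on one
    subject's training split, early-stopped on that subject's validation loss."""
    if not subject.train:
        raise ValidationError(f"subject {subject.subject_id}: empty training split")
    # work on a copy so the generic parameters stay reusable
    cls = type(model)
    from .autodiff import parameter
    copy = cls(model.config, params={k: parameter(p.data.copy())
                                     for k, p in model.params.items()})
    train_groups = _group_encode(subject.train, subject.scaler)
    val_groups = _group_encode(subject.val, subject.scaler)
    copy, history = train_model(copy, train_groups, val_groups, protocol,
                                seed=seed)
    return copy, history


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict_examples(model, examples, scaler: Scaler | None = None) -> np.ndarray:
    """Physical-unit predictions, order-aligned with ``examples``.  Works for
    neural models (needs the scaler) and for baselines (predict_batch)."""
    if hasattr(model, "predict_batch"):
        return model.predict_batch(examples)
    if scaler is None:
        raise ValueError("neural models need the subject's scaler")
    preds = np.empty(len(examples))
    for g in _group_encode(examples, scaler).values():
        est, _ = _forward(model, g["hist"], g["win"], g["extras"])
        preds[g["idx"]] = scaler.unscale(est.data[:, 0], "label")
    return preds


def _metrics(labels: np.ndarray, preds: np.ndarray) -> tuple[float, float]:
    err = preds - labels
    return float(np.sqrt(np.mean(err ** 2))), float(np.mean(np.abs(err)))


@dataclass
class EvalReport:
    """Per subject x seed x horizon RMSE/MAE in physical units (g or u).

    Rows with ``split == 'val'`` exist solely so best-seed selection can see
    validation MAE; aggregation methods only read test rows (mean) or the
    validation rows for seed selection (best)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject_id", "seed", "split", "horizon", "rmse", "mae", "n"]))

    def combine(self, other: "EvalReport") -> "EvalReport":
        frames = [f for f in (self.frame, other.frame) if not f.empty]
        if not frames:
            return EvalReport()
        return EvalReport(frame=pd.concat(frames, ignore_index=True))

    def _test_all(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["split"] == "test") & (f["horizon"] == "all")]

    def mean_score(self) -> dict:
        """Average over seeds within subject, then over subjects."""
        t = self._test_all()
        if t.empty:
            return {"rmse": np.nan, "mae": np.nan}
        per_subject = t.groupby("subject_id")[["rmse", "mae"]].mean()
        return {"rmse": float(per_subject["rmse"].mean()),
                "mae": float(per_subject["mae"].mean())}

    def best_score(self) -> dict:
        """Per subject, the seed with the best validation MAE; then averaged."""
        t = self._test_all()
        v = self.frame[(self.frame["split"] == "val") & (self.frame["horizon"] == "all")]
        rows = []
        for sid, grp in v.groupby("subject_id"):
            val_mae = dict(zip(grp["seed"], grp["mae"]))
            seed = select_best_seed(val_mae)
            sel = t[(t["subject_id"] == sid) & (t["seed"] == seed)]
            if not sel.empty:
                rows.append(sel.iloc[0])
        if not rows:
            return {"rmse": np.nan, "mae": np.nan}
        rows = pd.DataFrame(rows)
        return {"rmse": float(rows["rmse"].mean()), "mae": float(rows["mae"].mean())}

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EvalReport":
        frame = pd.read_csv(path, dtype={"horizon": str})
        frame["seed"] = frame["seed"].astype(int)
        return cls(frame=frame)


def select_best_seed(val_mae_by_seed: dict) -> int:
    """Pick the seed with the lowest validation MAE.  This function is the
    only model-selection path, and it sees validation metrics exclusively."""
    if not val_mae_by_seed:
        raise ValidationError("no validation metrics to select from")
    return min(sorted(val_mae_by_seed), key=lambda s: val_mae_by_seed[s])


def evaluate(models_per_seed: dict, subject: SubjectData,
             test_examples=None) -> EvalReport:
    """Score each seed's model on a subject's test split, per horizon and
    overall, plus the validation rows used for best-seed selection."""
    test = subject.test if test_examples is None else test_examples
    rows = []
    if not test:
        logger.warning("subject %s: empty test set, excluded from aggregation",
                       subject.subject_id)
        return EvalReport()
    test_labels = np.array([ex.label for ex in test])
    val_labels = np.array([ex.label for ex in subject.val])
    for seed, model in models_per_seed.items():
        preds = predict_examples(model, test, subject.scaler)
        rmse, mae = _metrics(test_labels, preds)
        rows.append({"subject_id": subject.subject_id, "seed": seed,
                     "split": "test", "horizon": "all", "rmse": rmse,
                     "mae": mae, "n": len(test)})
        taus = np.array([ex.tau for ex in test])
        for tau in sorted(set(taus)):
            sel = taus == tau
            rmse, mae = _metrics(test_labels[sel], preds[sel])
            rows.append({"subject_id": subject.subject_id, "seed": seed,
                         "split": "test", "horizon": str(tau), "rmse": rmse,
                         "mae": mae, "n": int(sel.sum())})
        if len(subject.val):
            vp = predict_examples(model, subject.val, subject.scaler)
            rmse, mae = _metrics(val_labels, vp)
            rows.append({"subject_id": subject.subject_id, "seed": seed,
                         "split": "val", "horizon": "all", "rmse": rmse,
                         "mae": mae, "n": len(subject.val)})
    return EvalReport(frame=pd.DataFrame(rows))


def compare_models(scores_a, scores_b, variant: str = "welch") -> float:
    """One-tailed t-test p-value for mean(A) < mean(B)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 scores per side")
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
        return 0.5
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"),
                          alternative="less")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-horizon transfer experiment
# ---------------------------------------------------------------------------

def horizon_transfer_experiment(subjects: list[SubjectData], scenario: str,
                                tau_list=(30, 45, 60, 75, 90),
                                protocol: TrainProtocol | None = None,
                                model_kind: str = "nbeats",
                                example_class: str = "inertial",
                                seed: int = 1, config=None,
                                min_train: int = 10) -> pd.DataFrame:
    """Does a model trained on all horizons transfer to a single horizon?

    For each tau in ``tau_list``, trains a tau-only model and evaluates both
    it and the all-horizon model on tau-only test examples (pooled over
    subjects).  Rows with too few tau-specific training examples are left
    missing.  Columns: each tau plus their average, for RMSE and MAE.
    """
    protocol = protocol or TrainProtocol()

    def restrict(subs, tau):
        out = []
        for s in subs:
            out.append(SubjectData(
                subject_id=s.subject_id, scaler=s.scaler,
                train=[e for e in s.train if e.tau == tau],
                val=[e for e in s.val if e.tau == tau],
                test=[e for e in s.test if e.tau == tau], record=s.record))
        return out

    model_all, _ = pretrain_global(subjects, scenario, example_class,
                                   model_kind, protocol, seed=seed, config=config)
    results = {("all_tau", m): {} for m in ("rmse", "mae")}
    results.update({("one_tau", m): {} for m in ("rmse", "mae")})
    for tau in tau_list:
        subs_tau = restrict(subjects, tau)
        test = [e for s in subs_tau for e in s.test]
        n_train = sum(len(s.train) for s in subs_tau)
        if not test or n_train < min_train:
            logger.warning("tau=%d: %d train / %d test examples; row missing",
                           tau, n_train, len(test))
            continue
        labels = np.array([e.label for e in test])
        preds_all = np.concatenate([
            predict_examples(model_all, s.test, s.scaler)
            for s in subs_tau if s.test])
        rmse, mae = _metrics(labels, preds_all)
        results[("all_tau", "rmse")][tau] = rmse
        results[("all_tau", "mae")][tau] = mae
        model_tau, _ = pretrain_global(subs_tau, scenario, example_class,
                                       model_kind, protocol, seed=seed,
                                       config=config)
        preds_tau = np.concatenate([
            predict_examples(model_tau, s.test, s.scaler)
            for s in subs_tau if s.test])
        rmse, mae = _metrics(labels, preds_tau)
        results[("one_tau", "rmse")][tau] = rmse
        results[("one_tau", "mae")][tau] = mae
    frame = pd.DataFrame(results).T
    frame = frame.reindex(columns=list(tau_list))
    frame["average"] = frame.mean(axis=1)
    frame.index.names = ["trained_on", "metric"]
    return frame


# ---------------------------------------------------------------------------
# Baseline convenience
# ---------------------------------------------------------------------------

def fit_baselines(subject: SubjectData):
    """(global-average, ToD-average) baselines on the subject's training events."""
    events = unique_events(subject.train)
    return fit_global(events), fit_tod(events)
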