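"""Reference predictors: global average and time-of-day average.

Both are fit per subject on training-split events only.  The global baseline
predicts the subject's mean label for every test example; the ToD baseline
keeps one mean per time-of-day window and answers with the window overlapping
the event time ``t+10``, falling back to the global mean for empty windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .example_builder import tod_interval
from .timeseries_core import ValidationError


def _label_wall(event):
    """Accept (label, wall_minutes) pairs or RecommendationExample-likes."""
    if hasattr(event, "label"):
        return float(event.label), int(event.wall_minutes)
    label, wall = event
    return float(label), int(wall)


@dataclass
class GlobalAverageModel:
    mu: float

    def predict(self, example=None) -> float:
        return self.mu

    def predict_batch(self, examples) -> np.ndarray:
        return np.full(len(examples), self.mu)


@dataclass
class ToDAverageModel:
    mu_k: dict = field(default_factory=dict)   # window -> mean label
    n_k: dict = field(default_factory=dict)    # window -> event count
    mu: float = 0.0                            # global fallback

    def predict(self, example) -> float:
        _, wall = _label_wall(example)
        k = tod_interval(wall)
        return self.mu_k.get(k, self.mu) if self.n_k.get(k, 0) > 0 else self.mu

    def predict_batch(self, examples) -> np.ndarray:
        return np.array([self.predict(e) for e in examples])


def fit_global(train_events) -> GlobalAverageModel:
    labels = [_label_wall(e)[0] for e in train_events]
    if not labels:
        raise ValidationError("no training events for global-average baseline")
    return GlobalAverageModel(mu=float(np.mean(labels)))


def fit_tod(train_events) -> ToDAverageModel:
    pairs = [_label_wall(e) for e in train_events]
    if not pairs:
        raise ValidationError("no training events for ToD-average baseline")
    labels = np.array([p[0] for p in pairs])
    windows = np.array([tod_interval(p[1]) for p in pairs])
    model = ToDAverageModel(mu=float(labels.mean()))
    for k in range(1, 6):
        sel = windows == k
        model.n_k[k] = int(sel.sum())
        if model.n_k[k]:
            model.mu_k[k] = float(labels[sel].mean())
    return model


def save_baseline(model, path) -> None:
    """Plain-text (JSON) serialization for either baseline."""
    import json
    if isinstance(model, GlobalAverageModel):
        payload = {"kind": "global_average", "mu": model.mu}
    else:
        payload = {"kind": "tod_average", "mu": model.mu,
                   "mu_k": {str(k): v for k, v in model.mu_k.items()},
                   "n_k": {str(k): v for k, v in model.n_k.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_baseline(path):
    import json
    with open(path) as fh:
        d = json.load(fh)
    if d["kind"] == "global_average":
        return GlobalAverageModel(mu=d["mu"])
    return ToDAverageModel(mu=d["mu"],
                           mu_k={int(k): v for k, v in d["mu_k"].items()},
                           n_k={int(k): v for k, v in d["n_k"].items()})


def unique_events(examples):
    """One (label, wall) entry per underlying event: the 13 horizon copies of
    an event share (subject, t), so baselines see each meal/bolus once."""
    seen, out = set(), []
    for ex in examples:
        key = (ex.subject_id, ex.t)
        if key not in seen:
            seen.add(key)
            out.append((ex.label, ex.wall_minutes))
    return out
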