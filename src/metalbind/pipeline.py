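"""End-to-end fragment classifier: PWM encoder + standardized MLP.

Fitting is a two-stage procedure on the same training fragments: the ten
position weight matrices (and their shared backgrounds) are fitted first,
the fragments are encoded with them, and the network is trained on the
encoded matrix.  Prediction encodes unseen fragments with the training-time
matrices, so evaluation folds never leak into the features.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from . import model as _model
from .features import PWMSet, encode_fragments, TRACKS, TRACK_CLASSES, fit_pwm, PositionWeightMatrix
from .model import ModelConfig, TrainedModel


class NotFittedError(RuntimeError):
    pass


class FragmentPipeline:
    """Fit on labelled fragments, predict binding probabilities for new ones."""

    def __init__(self, config: ModelConfig | None = None, background: str = "empirical"):
        self.config = config or ModelConfig()
        self.background = background
        self.pwms: PWMSet | None = None
        self.model: TrainedModel | None = None

    def clone(self, seed: int | None = None) -> "FragmentPipeline":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        return FragmentPipeline(config=cfg, background=self.background)

    def fit(self, fragments) -> "FragmentPipeline":
        fragments = list(fragments)
        self.pwms = PWMSet.fit(fragments, background=self.background)
        X, y = encode_fragments(fragments, self.pwms)
        self.model = _model.train(X, y, self.config)
        return self

    def predict(self, fragments) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, binary calls) for a fragment collection."""
        if self.pwms is None or self.model is None:
            raise NotFittedError("pipeline has not been fitted")
        X, _ = encode_fragments(fragments, self.pwms)
        return _model.predict(self.model, X)

    # -- persistence ------------------------------------------------------

    def save(self, directory) -> None:
        """Write the fitted pipeline: network JSON + PWMs as delimited text."""
        if self.pwms is None or self.model is None:
            raise NotFittedError("cannot save an unfitted pipeline")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _model.save_model(self.model, directory / "model.json")
        write_pwms(self.pwms, directory / "pwms.tsv")

    @classmethod
    def load(cls, directory) -> "FragmentPipeline":
        directory = Path(directory)
        trained = _model.load_model(directory / "model.json")
        pipe = cls(config=trained.config)
        pipe.model = trained
        pipe.pwms = read_pwms(directory / "pwms.tsv")
        pipe.background = pipe.pwms.background
        return pipe


def default_pipeline_factory(config: ModelConfig | None = None,
                             background: str = "empirical"):
    """Factory for per-fold pipelines; the argument seeds the network."""
    base = config or ModelConfig()

    def factory(seed: int) -> FragmentPipeline:
        return FragmentPipeline(config=replace(base, seed=seed), background=background)

    return factory


def write_pwms(pwms: PWMSet, path) -> None:
    """Long-format TSV: track, fitted_on, L, q, site, class, m, p, p0."""
    with open(path, "w") as fh:
        fh.write(f"# background={pwms.background}\n")
        fh.write("track\tfitted_on\tL\tq\tsite\tclass\tm\tp\tp0\n")
        for side in ("positive", "negative"):
            table = getattr(pwms, side)
            for track in TRACKS:
                pwm = table[track]
                for i in range(pwm.L):
                    for j, cls in enumerate(TRACK_CLASSES[track]):
                        fh.write(
                            f"{track}\t{side}\t{pwm.L}\t{pwm.q}\t{i}\t{cls}"
                            f"\t{float(pwm.m[i, j])!r}\t{float(pwm.p[i, j])!r}"
                            f"\t{float(pwm.p0[j])!r}\n"
                        )


def read_pwms(path) -> PWMSet:
    cells: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    background = "empirical"
    L = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# background="):
                background = line.strip().split("=", 1)[1]
                continue
            if line.startswith("track\t") or not line.strip():
                continue
            track, side, L_s, q_s, site, cls, m, p, p0 = line.rstrip("\n").split("\t")
            L, q = int(L_s), int(q_s)
            key = (track, side)
            if key not in cells:
                cells[key] = {
                    "m": np.zeros((L, q)),
                    "p": np.zeros((L, q)),
                    "p0": np.zeros(q),
                }
            j = TRACK_CLASSES[track].index(cls)
            cells[key]["m"][int(site), j] = float(m)
            cells[key]["p"][int(site), j] = float(p)
            cells[key]["p0"][j] = float(p0)
    pos, neg = {}, {}
    for (track, side), arrs in cells.items():
        pwm = PositionWeightMatrix(
            track=track, fitted_on=side, L=arrs["m"].shape[0],
            q=arrs["m"].shape[1], p=arrs["p"], p0=arrs["p0"], m=arrs["m"],
        )
        (pos if side == "positive" else neg)[track] = pwm
    return PWMSet(positive=pos, negative=neg, L=L, background=background)
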