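"""Map measured-muscle features onto model-muscle activations.

The face model has ten muscle groups per side, but only seven can be
measured with surface electrodes.  The missing groups are composed from
anatomically neighbouring measurements:

    OOP = 0.50 * (OOS + OOI)        (peripheral orbicularis oris)
    OOM = 0.10 * (OOP + OOI)        (marginal orbicularis oris)
    BUC = 0.50 * (RIS + ZYG)        (buccinator, picked up by RIS/ZYG sites)
    LAO = 0.75 * LLSAN              (levator anguli oris)
    DLI = 0.75 * DAO                (depressor labii inferior)

while MEN, ZYG, RIS, DAO and LLSAN pass through unchanged.  Outputs are
clipped to the model's activation range [0, 1].

Three activation strategies turn the 20-channel feature set into model
input: ``act_all`` keeps every channel; ``act_3`` keeps only the three
muscles with the largest time-variance of the bilaterally averaged
feature (each side keeps its own trace); ``act_rel`` keeps the muscles
considered relevant for the instruction (``muscles.RELEVANT_MUSCLES``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureSeries
from .muscles import (
    MEASURED_MUSCLES,
    MODEL_MUSCLES,
    RELEVANT_MUSCLES,
    SIDES,
    check_instruction,
    model_labels,
)

STRATEGIES: tuple[str, ...] = ("act_all", "act_3", "act_rel")

# Composition factors for the unmeasured muscle groups.
OOP_FACTOR = 0.50
OOM_FACTOR = 0.10
BUC_FACTOR = 0.50
LAO_FACTOR = 0.75
DLI_FACTOR = 0.75


@dataclass
class ActivationSet:
    """Model activation trajectories, 20 channels in [0, 1]."""

    values: np.ndarray
    times: np.ndarray
    labels: list[str]
    strategy: str
    instruction: str = ""
    repetition: int = 0
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per activation channel required")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("activations must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _side_block(feat: FeatureSeries, side: str) -> dict[str, np.ndarray]:
    """Extract one side's measured-muscle traces, keyed by muscle name."""
    out = {}
    for m in MEASURED_MUSCLES:
        label = f"{m}_{side}"
        if label not in feat.labels:
            raise ValueError(f"missing measured channel {label!r}")
        out[m] = feat.values[feat.labels.index(label)]
    return out


def derive_model_muscles(feat: FeatureSeries) -> FeatureSeries:
    """Compose the 20 model-muscle traces from 14 measured traces.

    Requires normalised input features; the output is clipped to [0, 1].
    """
    blocks = []
    for side in SIDES:
        g = _side_block(feat, side)
        oop = OOP_FACTOR * (g["OOS"] + g["OOI"])
        derived = {
            "OOP": oop,
            "OOM": OOM_FACTOR * (oop + g["OOI"]),
            "BUC": BUC_FACTOR * (g["RIS"] + g["ZYG"]),
            "LAO": LAO_FACTOR * g["LLSAN"],
            "DLI": DLI_FACTOR * g["DAO"],
            "MEN": g["MEN"],
            "ZYG": g["ZYG"],
            "RIS": g["RIS"],
            "DAO": g["DAO"],
            "LLSAN": g["LLSAN"],
        }
        blocks.append(np.stack([derived[m] for m in MODEL_MUSCLES]))
    values = np.clip(np.concatenate(blocks, axis=0), 0.0, 1.0)
    return replace(feat, values=values, labels=model_labels())


def bilateral_average(feat20: FeatureSeries) -> FeatureSeries:
    """Frame-wise mean of left and right traces, 20 -> 10 channels."""
    expected = model_labels()
    if list(feat20.labels) != expected:
        raise ValueError(
            "bilateral_average requires the canonical 20-channel order "
            "(left block then right block)"
        )
    n = len(MODEL_MUSCLES)
    values = 0.5 * (feat20.values[:n] + feat20.values[n:])
    return replace(feat20, values=values, labels=list(MODEL_MUSCLES))


def select_top3(feat10: FeatureSeries) -> list[str]:
    """The three muscles with largest time-variance, descending.

    Ties break on the canonical muscle order (stable sort).
    """
    if feat10.values.shape[0] < 3:
        raise ValueError("need at least 3 channels to select the top 3")
    variances = np.var(feat10.values, axis=1)
    if not np.all(np.isfinite(variances)):
        raise ValueError("non-finite variance encountered")
    canon = [MODEL_MUSCLES.index(m) for m in feat10.labels]
    order = sorted(
        range(len(feat10.labels)),
        key=lambda j: (-variances[j], canon[j]),
    )
    return [feat10.labels[j] for j in order[:3]]


def apply_strategy(
    feat20: FeatureSeries,
    strategy: str,
    instruction: str | None = None,
) -> ActivationSet:
    """Build an ActivationSet from 20-channel features under a strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    if list(feat20.labels) != model_labels():
        raise ValueError("apply_strategy requires the canonical "
                         "20-channel order")
    values = np.clip(feat20.values.copy(), 0.0, 1.0)
    selected: list[str] = []
    if strategy == "act_3":
        selected = select_top3(bilateral_average(feat20))
    elif strategy == "act_rel":
        instruction = check_instruction(
            instruction if instruction is not None else feat20.instruction
        )
        selected = list(RELEVANT_MUSCLES[instruction])
    if strategy in ("act_3", "act_rel"):
        keep = {f"{m}_{s}" for m in selected for s in SIDES}
        for j, label in enumerate(feat20.labels):
            if label not in keep:
                values[j] = 0.0
    return ActivationSet(
        values=values,
        times=feat20.times,
        labels=list(feat20.labels),
        strategy=strategy,
        instruction=instruction or feat20.instruction,
        repetition=feat20.repetition,
        selected=selected,
    )
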