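"""Sliding-window supervised examples and the train/validation/test split.

Each example packs the last two hours of every channel (24 five-minute steps,
t−23…t) as the input block and the glucose reading one hour ahead (t+12) as
the scalar target.  Windows slide one step at a time, and a window is only
admitted when all 24 input steps and the target step are valid on the joint
mask — so no example ever spans a CGM gap or a night-time accelerometer
removal.  Examples are then assigned at random to train/validation/test with
60/20/20 proportions, the splitting the experiments harness shares across
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import MultiGridSignal

__all__ = ["WindowExample", "WindowSet", "build_windows", "split_windows", "SPLIT_RATIOS"]

SPLIT_RATIOS = {"train": 0.6, "validation": 0.2, "test": 0.2}


@dataclass(frozen=True)
class WindowExample:
    """One supervised example: 24×C inputs, glucose target 12 steps ahead."""

    x: np.ndarray  # (input_len, n_channels)
    y: float  # mmol/L
    t_index: int  # grid index of the last input step


@dataclass
class WindowSet:
    """A collection of window examples with channel names and split labels."""

    examples: list[WindowExample]
    channel_names: list[str]
    split: np.ndarray = field(default=None)  # type: ignore[assignment]  # str per example

    def __len__(self) -> int:
        return len(self.examples)

    def tensors(self, subset: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (X, y) arrays, optionally restricted to one split."""
        idx = range(len(self.examples))
        if subset is not None:
            if self.split is None:
                raise ValueError("window set has not been split")
            idx = [i for i in idx if self.split[i] == subset]
        X = np.stack([self.examples[i].x for i in idx]) if idx else np.empty((0, 0, 0))
        y = np.array([self.examples[i].y for i in idx])
        return X, y

    def select_channels(self, names: list[str]) -> "WindowSet":
        """A window set restricted to a subset of channels (split preserved)."""
        cols = [self.channel_names.index(n) for n in names]
        examples = [
            WindowExample(ex.x[:, cols], ex.y, ex.t_index) for ex in self.examples
        ]
        return WindowSet(examples, list(names), self.split)

    def save(self, path: str | Path) -> None:
        X = np.stack([ex.x for ex in self.examples])
        y = np.array([ex.y for ex in self.examples])
        t = np.array([ex.t_index for ex in self.examples])
        np.savez(
            path,
            x=X,
            y=y,
            t_index=t,
            channel_names=np.array(self.channel_names),
            split=self.split if self.split is not None else np.array([]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        with np.load(path, allow_pickle=False) as data:
            examples = [
                WindowExample(x, float(y), int(t))
                for x, y, t in zip(data["x"], data["y"], data["t_index"])
            ]
            split = data["split"] if data["split"].size else None
            return cls(examples, [str(n) for n in data["channel_names"]], split)


def build_windows(
    joint: MultiGridSignal,
    glucose_channel: str = "glucose",
    input_len: int = 24,
    horizon: int = 12,
) -> list[WindowExample]:
    """Enumerate all admissible sliding windows over the joint signal.

    A window ending at grid index t is admissible when indices t−input_len+1…t
    and the target index t+horizon are all valid on the joint mask.  Only the
    target step is checked beyond the input block; the intermediate steps
    t+1…t+horizon−1 are not required.
    """
    if glucose_channel not in joint.channel_index:
        raise ValueError(f"glucose channel {glucose_channel!r} not present")
    if input_len < 1 or horizon < 1:
        raise ValueError("input_len and horizon must be >= 1")
    n = joint.grid.length
    mask = joint.mask
    glucose = joint.channel(glucose_channel)

    # valid_block[t] = all of t-input_len+1 .. t valid
    csum = np.concatenate([[0], np.cumsum(mask.astype(int))])
    examples: list[WindowExample] = []
    for t in range(input_len - 1, n - horizon):
        if csum[t + 1] - csum[t + 1 - input_len] != input_len:
            continue
        if not mask[t + horizon]:
            continue
        x = joint.values[t - input_len + 1 : t + 1, :].copy()
        examples.append(WindowExample(x, float(glucose[t + horizon]), t))
    return examples


def split_windows(
    examples: list[WindowExample],
    channel_names: list[str],
    seed: int,
    ratios: dict[str, float] = SPLIT_RATIOS,
) -> WindowSet:
    """Randomly assign examples to train/validation/test splits.

    Counts are ⌊n·ratio⌋ for validation and test with the remainder going to
    train; the assignment is a seeded uniform permutation, so one seed always
    reproduces one split.
    """
    n = len(examples)
    if n < 5:
        raise ValueError(f"need at least 5 examples to split, got {n}")
    n_val = int(np.floor(n * ratios["validation"]))
    n_test = int(np.floor(n * ratios["test"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_val]] = "validation"
    split[order[n_val : n_val + n_test]] = "test"
    split[order[n_val + n_test :]] = "train"
    return WindowSet(list(examples), list(channel_names), split.astype(str))
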