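"""Transformation of three-frame windows into the five model-input formats.

Given a window of three consecutive frames (1, 2, 3 oldest to newest) and k
selected features, the formats are:

* ``A1`` — absolute feature values at the newest frame (k values),
* ``A2`` — absolutes at frames 2 and 3 (2k),
* ``A3`` — absolutes at all three frames (3k),
* ``P1`` — per-feature percent change from frame 1 to frame 2 (k),
* ``P2`` — P1 plus the percent change from frame 2 to frame 3 (2k).

Percent changes are signed fractions ``(x_{n+1} - x_n) / x_n`` (denominator
= preceding frame by default; the variant dividing by the following frame is
available via ``denominator="following"``).  Dividing consecutive
differences by the feature's own magnitude removes per-feature scaling, so
P-type inputs are invariant under positive rescaling of any feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INPUT_TYPES = ("A1", "A2", "A3", "P1", "P2")


@dataclass
class InputVector:
    """One window in one input format."""

    window_id: int
    input_type: str
    feature_names: list[str]
    values: np.ndarray
    label: str = "unlabeled"


def input_length(input_type: str, k: int) -> int:
    """Vector length of an input type for k features."""
    return {"A1": k, "A2": 2 * k, "A3": 3 * k, "P1": k, "P2": 2 * k}[input_type]


def percent_change(x_n: float, x_n1: float, denominator: str = "preceding") -> float:
    """Signed fractional change between consecutive frames.

    ``preceding`` (default): (x_{n+1} - x_n) / x_n;
    ``following``: (x_{n+1} - x_n) / x_{n+1}.
    A zero denominator raises ZeroDivisionError — callers drop the window.
    """
    denom = x_n if denominator == "preceding" else x_n1
    if denom == 0:
        raise ZeroDivisionError("zero denominator in percent change")
    return (x_n1 - x_n) / denom


def _column_names(input_type: str, feature_names: list[str]) -> list[str]:
    if input_type == "A1":
        return [f"{f}@f3" for f in feature_names]
    if input_type == "A2":
        return [f"{f}@f{i}" for i in (2, 3) for f in feature_names]
    if input_type == "A3":
        return [f"{f}@f{i}" for i in (1, 2, 3) for f in feature_names]
    if input_type == "P1":
        return [f"{f}@pct(1-2)" for f in feature_names]
    if input_type == "P2":
        return [f"{f}@pct(1-2)" for f in feature_names] + [
            f"{f}@pct(2-3)" for f in feature_names
        ]
    raise ValueError(f"unknown input type {input_type!r}")


def make_input(
    window: pd.DataFrame,
    input_type: str,
    feature_names: list[str],
    denominator: str = "preceding",
) -> InputVector:
    """Transform one three-frame window (rows ordered oldest -> newest).

    ``window`` must contain exactly three rows and every requested feature
    column.  Raises ``ValueError`` on malformed windows and
    ``ZeroDivisionError`` when a percent-change denominator is zero; batch
    callers catch these and drop the window.
    """
    if input_type not in INPUT_TYPES:
        raise ValueError(f"unknown input type {input_type!r}")
    if len(window) != 3:
        raise ValueError("a window must contain exactly three frames")
    missing = [f for f in feature_names if f not in window.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")

    x = window[feature_names].to_numpy(dtype=float)  # rows: frames 1..3
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature value in window")

    if input_type == "A1":
        values = x[2]
    elif input_type == "A2":
        values = np.concatenate([x[1], x[2]])
    elif input_type == "A3":
        values = np.concatenate([x[0], x[1], x[2]])
    else:
        p12 = np.array(
            [percent_change(x[0, j], x[1, j], denominator) for j in range(x.shape[1])]
        )
        if input_type == "P1":
            values = p12
        else:
            p23 = np.array(
                [percent_change(x[1, j], x[2, j], denominator) for j in range(x.shape[1])]
            )
            values = np.concatenate([p12, p23])

    wid = int(window["window_id"].iloc[0]) if "window_id" in window.columns else -1
    return InputVector(
        window_id=wid,
        input_type=input_type,
        feature_names=list(feature_names),
        values=values,
    )


def make_inputs_table(
    windows_long: pd.DataFrame,
    input_type: str,
    feature_names: list[str],
    denominator: str = "preceding",
) -> tuple[pd.DataFrame, int]:
    """Transform every window of a long-format window table.

    Returns ``(table, n_dropped)`` where the table has one row per valid
    window, indexed by ``window_id``, with stable feature@frame /
    feature@pct(i-j) columns; windows with zero percent-change denominators
    or non-finite values are dropped (counted and logged).
    """
    cols = _column_names(input_type, list(feature_names))
    rows: list[np.ndarray] = []
    ids: list[int] = []
    dropped = 0
    for wid, sub in windows_long.groupby("window_id"):
        sub = sub.sort_values("slot")
        try:
            iv = make_input(sub, input_type, list(feature_names), denominator)
        except (ZeroDivisionError, ValueError):
            dropped += 1
            continue
        rows.append(iv.values)
        ids.append(int(wid))
    if dropped:
        logger.info("dropped %d invalid windows for %s inputs", dropped, input_type)
    table = pd.DataFrame(rows, columns=cols, index=pd.Index(ids, name="window_id"))
    return table, dropped
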