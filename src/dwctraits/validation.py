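"""Scoring extraction output against hand-labelled gold standards.

A record is a true positive for a trait when the gold standard marks the
trait present and the prediction matches it (presence and, for
measurements, exact value equality after the two-decimal truncation); a
false positive when predicted but absent from gold; a false negative when
present in gold but not predicted; a true negative otherwise. Gold entries
flagged as keyless-implied (values with no key naming the trait, e.g. a
bare "adult") are tallied separately and excluded from the confusion
matrix, mirroring how such cases are compiled but kept out of error rates
during manual validation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

TRAITS = ("length", "mass", "sex", "life stage")


class ValidationError(ValueError):
    """Prediction and gold record ids do not line up."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts over one assessed trait."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class ValidationMetrics:
    """Sensitivity, specificity and Matthews correlation, 3-decimal."""

    tpr: float
    tnr: float
    mcc: float


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``; returns 0
    when any denominator factor is zero (common convention for degenerate
    matrices).
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def rates(cm: ConfusionMatrix) -> ValidationMetrics:
    """TPR, TNR and MCC, each rounded to three decimals for reporting."""
    tpr = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    tnr = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return ValidationMetrics(
        tpr=round(tpr, 3), tnr=round(tnr, 3), mcc=round(mcc(cm), 3)
    )


@dataclass(frozen=True)
class GoldLabel:
    """Hand-labelled truth for one (record, trait)."""

    present: bool
    value: object = None  # harmonized value (float) or categorical token
    units: str = ""
    keyless_implied: bool = False


def _values_match(gold_value, pred_value) -> bool:
    if gold_value is None:
        return True  # presence-only gold
    if isinstance(gold_value, (int, float)) and isinstance(pred_value, (int, float)):
        return float(gold_value) == float(pred_value)
    if pred_value is None:
        return False
    return str(gold_value).strip().lower() == str(pred_value).strip().lower()


def score_against_gold(
    predictions: Mapping[str, tuple[bool, object]],
    gold: Mapping[str, GoldLabel],
    trait: str = "",
) -> tuple[ConfusionMatrix, int]:
    """Score per-record predictions for one trait against gold labels.

    Parameters
    ----------
    predictions
        record_id -> (predicted_present, predicted_value).
    gold
        record_id -> :class:`GoldLabel`.

    Returns
    -------
    (ConfusionMatrix, keyless_tally)
        Keyless-implied gold entries are excluded from the matrix and
        counted in the tally.

    Raises
    ------
    ValidationError
        If the two id sets differ (offenders listed).
    """
    if set(predictions) != set(gold):
        only_pred = sorted(set(predictions) - set(gold))[:10]
        only_gold = sorted(set(gold) - set(predictions))[:10]
        raise ValidationError(
            f"record id mismatch for trait {trait or '?'}: "
            f"only in predictions {only_pred}, only in gold {only_gold}"
        )
    tp = fp = tn = fn = keyless = 0
    for rid, label in gold.items():
        pred_present, pred_value = predictions[rid]
        if label.keyless_implied:
            keyless += 1
            continue
        if label.present and pred_present and _values_match(label.value, pred_value):
            tp += 1
        elif pred_present and not label.present:
            fp += 1
        elif label.present and not pred_present:
            fn += 1
        elif label.present and pred_present:
            fp += 1  # extracted, but the wrong value: a commission error
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn), keyless


def sample_validation_set(
    records: Sequence, n: int, seed: int
) -> list:
    """Uniform sample without replacement: random key, sort, take first n.

    Implemented literally as the manual procedure it reproduces: attach a
    column of random numbers, sort on it, keep the first ``n`` rows.
    """
    if n > len(records):
        raise ValueError(f"n={n} exceeds population size {len(records)}")
    rng = np.random.default_rng(seed)
    keys = rng.random(len(records))
    order = np.argsort(keys, kind="stable")
    return [records[i] for i in order[:n]]


def write_gold(gold: Mapping[str, Mapping[str, GoldLabel]], path: str | Path) -> None:
    """Write gold labels as CSV: record_id, trait, present, value, units, keyless."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "trait", "present", "value", "units", "keyless_implied"])
        for rid, traits in gold.items():
            for trait, label in traits.items():
                value = "" if label.value is None else label.value
                if isinstance(value, float) and value == int(value):
                    value = int(value)
                w.writerow([
                    rid, trait,
                    "true" if label.present else "false",
                    value, label.units,
                    "true" if label.keyless_implied else "false",
                ])


def read_gold(path: str | Path) -> dict[str, dict[str, GoldLabel]]:
    """Read gold labels written by :func:`write_gold` (round-trip inverse)."""
    out: dict[str, dict[str, GoldLabel]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            raw = row["value"]
            value: object
            if raw == "":
                value = None
            else:
                try:
                    value = float(raw)
                except ValueError:
                    value = raw
            out.setdefault(row["record_id"], {})[row["trait"]] = GoldLabel(
                present=row["present"] == "true",
                value=value,
                units=row["units"],
                keyless_implied=row["keyless_implied"] == "true",
            )
    return out
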