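"""Tab-separated readers and writers for parameter, activity, distribution
and region tables.

All files are UTF-8 TSV with a header row; values are written with 17
significant digits so that parameter tables round-trip bit-exactly through
text.  Unknown columns in a parameter table survive a read/write cycle.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import Alphabet, ModelSpec, ParameterVector, feature_order
from .parametric import PositionDistribution

FLOAT_FORMAT = "%.17g"


def _infer_alphabet(labels: pd.Series) -> Alphabet:
    chars = sorted({c for lab in labels for c in lab if c != "*"})
    return Alphabet(tuple(chars))


def read_parameter_table(path: str | Path, alphabet: Alphabet | None = None) -> ParameterVector:
    """Read a parameter table (columns ``feature``, ``order``, ``value``).

    The set of feature labels in the file defines the model's active
    features.  If no alphabet is given it is inferred as the sorted set of
    non-wildcard characters appearing in the labels.  Extra columns are kept
    on the returned vector (``extra_columns``) and re-emitted on write.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature": str}, float_precision="round_trip")
    for col in ("feature", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    labels = df["feature"]
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate feature label {dup!r}")
    lengths = labels.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: inconsistent label lengths {sorted(lengths.tolist())}"
        )
    if alphabet is None:
        alphabet = _infer_alphabet(labels)
    if "order" in df.columns:
        for lab, order in zip(labels, df["order"]):
            expected = feature_order(lab)
            if int(order) != expected:
                raise ValueError(
                    f"{path}: feature {lab!r} has order column {int(order)} "
                    f"but the label implies order {expected}"
                )
    spec = ModelSpec.from_features(alphabet, int(lengths[0]), labels.tolist())
    mapping = dict(zip(labels, df["value"].astype(float)))
    pv = ParameterVector.from_dict(spec, mapping)
    extras = [c for c in df.columns if c not in ("feature", "order", "value")]
    if extras:
        pv.extra_columns = df.set_index("feature")[extras]
    return pv


def write_parameter_table(pv: ParameterVector, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "feature": pv.spec.features,
            "order": pv.spec.orders,
            "value": pv.values,
        }
    )
    extra = getattr(pv, "extra_columns", None)
    if extra is not None:
        df = df.join(extra, on="feature")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str}, float_precision="round_trip")
    for col in ("sequence", "activity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_activity_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_distribution_table(
    path: str | Path, alphabet: Alphabet, length: int
) -> PositionDistribution:
    """Read a position-specific probability table (``position``,
    ``character``, ``probability``; positions 1-based).

    A (position, character) pair omitted from the file defaults to
    probability 0 if that position has explicit entries, and the whole
    position defaults to uniform if it has none.
    """
    df = pd.read_csv(path, sep="\t", dtype={"character": str}, float_precision="round_trip")
    for col in ("position", "character", "probability"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    probs = np.zeros((length, alphabet.size))
    seen_positions = set()
    for _, row in df.iterrows():
        pos = int(row["position"])
        if not 1 <= pos <= length:
            raise ValueError(f"{path}: position {pos} out of range 1..{length}")
        probs[pos - 1, alphabet.index(str(row["character"]))] = float(row["probability"])
        seen_positions.add(pos)
    for l in range(1, length + 1):
        if l not in seen_positions:
            probs[l - 1, :] = 1.0 / alphabet.size
    return PositionDistribution(alphabet, probs)


def write_distribution_table(p: PositionDistribution, path: str | Path) -> None:
    rows = []
    for l in range(p.length):
        for j, c in enumerate(p.alphabet.characters):
            rows.append(
                {"position": l + 1, "character": c, "probability": p.probs[l, j]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_region_table(path: str | Path) -> dict[int, str]:
    """Read a region definition (columns ``position``,
    ``allowed_characters``) into a map of 1-based position -> characters."""
    df = pd.read_csv(path, sep="\t", dtype={"allowed_characters": str})
    for col in ("position", "allowed_characters"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[int, str] = {}
    for _, row in df.iterrows():
        pos = int(row["position"])
        if pos in out:
            raise ValueError(f"{path}: duplicate position {pos}")
        chars = str(row["allowed_characters"])
        if not chars:
            raise ValueError(f"{path}: position {pos}: empty allowed character set")
        out[pos] = chars
    return out


def table_to_json(path_tsv: str | Path, path_json: str | Path) -> None:
    """Mirror a written TSV as a JSON array of row objects."""
    pd.read_csv(path_tsv, sep="\t").to_json(path_json, orient="records", indent=1)
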