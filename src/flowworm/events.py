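"""Per-cell event tables and boolean gate masks.

The :class:`EventTable` is the carrier for list-mode cytometry data: one row
per measured cell, one named column per channel (all values on a linear
fluorescence scale).  Gate masks produced during preprocessing attach to the
table by name so that downstream region schemes can refer to them in boolean
gate-context formulas such as ``((R2 AND R4 AND R5) OR R3)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventTable", "GateMask", "combine_gates"]

#: Canonical channel roles used throughout the pipeline.
CANONICAL_CHANNELS = ("dna", "dna_width", "phh3", "cyclin_a2", "cyclin_b1", "ssc")


@dataclass
class GateMask:
    """A named per-event boolean gate.

    Parameters
    ----------
    name:
        Gate identifier (``R2``, ``R3`` ... in the preprocessing chain).
    mask:
        Boolean array, one entry per event.
    definition:
        Human-readable description of how the gate was built; written to the
        gating log so the audit trail is reproducible.
    """

    name: str
    mask: np.ndarray
    definition: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return self.mask.size

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "GateMask") -> "GateMask":
        return GateMask(f"({self.name} AND {other.name})", self.mask & other.mask)

    def __or__(self, other: "GateMask") -> "GateMask":
        return GateMask(f"({self.name} OR {other.name})", self.mask | other.mask)

    def __invert__(self) -> "GateMask":
        return GateMask(f"(NOT {self.name})", ~self.mask)


class EventTable:
    """Named per-event measurement arrays plus attached gate masks.

    Thin wrapper around a :class:`pandas.DataFrame`; channels are columns.
    ``metadata`` records provenance (source file, transforms applied,
    background-subtraction coefficients, ...).
    """

    def __init__(self, data: pd.DataFrame, metadata: dict | None = None):
        if data.isna().any().any():
            raise ValueError("event table must not contain missing values")
        self.data = data.reset_index(drop=True)
        self.metadata: dict = dict(metadata or {})
        self.masks: dict[str, GateMask] = {}

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __contains__(self, channel: str) -> bool:
        return channel in self.data.columns

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    def require(self, *channels: str) -> None:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not present; available: {self.channels}"
            )

    # -- masks -------------------------------------------------------------
    def add_mask(self, gate: GateMask) -> GateMask:
        if len(gate) != self.n_events:
            raise ValueError(
                f"gate {gate.name!r} has {len(gate)} entries for {self.n_events} events"
            )
        self.masks[gate.name] = gate
        return gate

    def subset(self, mask: np.ndarray) -> "EventTable":
        """New table holding only the events where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        out = EventTable(self.data.loc[mask], metadata=dict(self.metadata))
        for gate in self.masks.values():
            out.masks[gate.name] = GateMask(gate.name, gate.mask[mask], gate.definition)
        return out

    def with_channel(self, channel: str, values: np.ndarray) -> "EventTable":
        """Copy of the table with ``channel`` replaced/added (masks kept)."""
        data = self.data.copy()
        data[channel] = np.asarray(values, dtype=float)
        out = EventTable(data, metadata=dict(self.metadata))
        out.masks = dict(self.masks)
        return out

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path, include_masks: bool = True) -> None:
        data = self.data.copy()
        if include_masks:
            for gate in self.masks.values():
                data[f"gate_{gate.name}"] = gate.mask.astype(int)
        data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mapping: dict[str, str] | None = None) -> "EventTable":
        data = pd.read_csv(path)
        if mapping:
            data = data.rename(columns=mapping)
        gate_cols = [c for c in data.columns if c.startswith("gate_")]
        table = cls(data.drop(columns=gate_cols), metadata={"source": str(path)})
        for col in gate_cols:
            table.add_mask(GateMask(col[len("gate_"):], data[col].to_numpy(dtype=bool)))
        return table


# -- boolean gate algebra ----------------------------------------------------

_TOKEN = re.compile(r"\s*(AND|OR|NOT|\(|\)|[A-Za-z_]\w*)\s*", re.IGNORECASE)


def combine_gates(masks, expression: str, name: str | None = None) -> GateMask:
    """Evaluate a boolean AND/OR/NOT formula over named gate masks.

    ``masks`` may be a list of :class:`GateMask` or a ``{name: GateMask}``
    mapping.  The formula is evaluated element-wise; names are
    case-sensitive, operators are not.

    >>> combine_gates([r2, r3, r4, r5], "((R2 AND R4 AND R5) OR R3)")
    """
    if not isinstance(masks, dict):
        masks = {m.name: m for m in masks}
    pos = 0
    pieces: list[str] = []
    length = None
    for gate in masks.values():
        if length is None:
            length = len(gate)
        elif len(gate) != length:
            raise ValueError("gate masks have unequal lengths")
    while pos < len(expression):
        m = _TOKEN.match(expression, pos)
        if not m:
            raise ValueError(f"bad token in gate expression at: {expression[pos:]!r}")
        tok = m.group(1)
        upper = tok.upper()
        if upper == "AND":
            pieces.append("&")
        elif upper == "OR":
            pieces.append("|")
        elif upper == "NOT":
            pieces.append("~")
        elif tok in "()":
            pieces.append(tok)
        else:
            if tok not in masks:
                raise KeyError(f"gate {tok!r} not among {sorted(masks)}")
            pieces.append(f"_g[{tok!r}].mask")
        pos = m.end()
    result = eval(" ".join(pieces), {"__builtins__": {}}, {"_g": masks})  # noqa: S307
    return GateMask(name or expression, np.asarray(result, dtype=bool), expression)
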