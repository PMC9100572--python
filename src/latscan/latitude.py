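"""Maturity-scaled latitude assignment.

Latitude of origin is used as a proxy for relative flowering time. Each
accession's latitude is assigned either by rescaling its breeder-provided
maturity score onto the north-south latitudinal span of its state of origin
("maturity-scaled latitude"), or, when no maturity score is available, by the
centroidal latitude of the state ("centroidal latitude").

Within one breeding program the earliest-maturing line (lowest relative
maturity, or fewest days to maturity) maps to the state's northern border and
the latest-maturing line to the southern border; intermediate scores are
linearly interpolated:

    lat(m) = north - (m - m_min) / (m_max - m_min) * (north - south)

Programs with a single scored line or zero score range are degenerate and fall
back to the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATURITY_SCALED = "maturity-scaled latitude"
CENTROIDAL = "centroidal latitude"

#: Valid kinds for maturity scores: breeder relative-maturity (decimal, lower =
#: earlier) or days to maturity (integer-ish, fewer = earlier). Both rescale
#: identically: the minimum score maps to the northern border.
SCORE_KINDS = ("RM", "days")


@dataclass(frozen=True)
class StateSpan:
    """North/south border and centroid latitude of a US state, decimal °N."""

    name: str
    north: float
    south: float
    centroid: float

    def __post_init__(self) -> None:
        if not self.north > self.south:
            raise ValueError(
                f"state {self.name!r}: north border ({self.north}) must exceed "
                f"south border ({self.south})"
            )
        if not (self.south <= self.centroid <= self.north):
            raise ValueError(
                f"state {self.name!r}: centroid {self.centroid} outside "
                f"[{self.south}, {self.north}]"
            )


class StateLatitudes:
    """Lookup table of state latitudinal spans."""

    def __init__(self, spans: list[StateSpan]):
        self._spans = {s.name: s for s in spans}

    def __getitem__(self, state: str) -> StateSpan:
        try:
            return self._spans[state]
        except KeyError:
            known = ", ".join(sorted(self._spans))
            raise KeyError(f"unknown state {state!r}; known states: {known}") from None

    def __contains__(self, state: str) -> bool:
        return state in self._spans

    def __iter__(self):
        return iter(self._spans.values())

    @classmethod
    def from_csv(cls, path) -> "StateLatitudes":
        df = pd.read_csv(path)
        return cls(
            [
                StateSpan(r["state"], float(r["north"]), float(r["south"]), float(r["centroid"]))
                for _, r in df.iterrows()
            ]
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(s.name, s.north, s.south, s.centroid) for s in self],
            columns=["state", "north", "south", "centroid"],
        ).to_csv(path, index=False)


def scale_program_latitudes(scores, span: StateSpan) -> np.ndarray:
    """Rescale one program's maturity scores onto the state's latitude span.

    Parameters
    ----------
    scores : array-like of float
        Maturity scores (RM or days to maturity) for the lines of a single
        breeding program within a single state. Must contain at least two
        distinct values.
    span : StateSpan
        Border latitudes of the program's state.

    Returns
    -------
    ndarray of assigned latitudes, one per score. The minimum score maps
    exactly to ``span.north``, the maximum to ``span.south``.
    """
    m = np.asarray(scores, dtype=float)
    if m.size < 2:
        raise ValueError("degenerate program: need at least two scored lines")
    lo, hi = m.min(), m.max()
    if hi == lo:
        raise ValueError("degenerate program: zero maturity-score range")
    return span.north - (m - lo) / (hi - lo) * (span.north - span.south)


def assign_centroid(span: StateSpan) -> float:
    """Centroidal latitude fallback for lines without usable maturity info."""
    return span.centroid


def assign_latitudes(
    metadata: pd.DataFrame,
    states: StateLatitudes,
    *,
    state_col: str = "state",
    program_col: str = "program",
    score_col: str = "maturity_score",
    score_kind_col: str = "score_kind",
) -> pd.DataFrame:
    """Assign a latitude and latitude type to every accession.

    Scaling groups are (state, program) when a program is recorded, else the
    state alone. Lines in degenerate groups (a single scored line, or all
    scores tied) and lines without a score receive the state centroid. A group
    mixing RM and days-to-maturity scores is rejected.

    Returns a copy of ``metadata`` with ``LATITUDE`` and ``LATITUDE_TYPE``
    columns appended.
    """
    out = metadata.copy()
    out["LATITUDE"] = np.nan
    out["LATITUDE_TYPE"] = CENTROIDAL

    for _, rows in out.groupby(
        [out[state_col], out[program_col].fillna("")]
        if program_col in out.columns
        else [out[state_col]],
        sort=False,
    ):
        state = rows[state_col].iloc[0]
        span = states[state]
        scored = rows[rows[score_col].notna()] if score_col in rows else rows.iloc[0:0]
        if score_kind_col in rows.columns and len(scored) > 0:
            kinds = set(scored[score_kind_col].dropna())
            if len(kinds) > 1:
                raise ValueError(
                    f"program {rows[program_col].iloc[0]!r} in {state!r} mixes "
                    f"maturity score kinds {sorted(kinds)}; one kind per program"
                )
        degenerate = len(scored) < 2 or scored[score_col].nunique() == 1
        if not degenerate:
            lats = scale_program_latitudes(scored[score_col].to_numpy(float), span)
            out.loc[scored.index, "LATITUDE"] = lats
            out.loc[scored.index, "LATITUDE_TYPE"] = MATURITY_SCALED
        unscaled = rows.index.difference(scored.index if not degenerate else rows.iloc[0:0].index)
        out.loc[unscaled, "LATITUDE"] = assign_centroid(span)
        out.loc[unscaled, "LATITUDE_TYPE"] = CENTROIDAL

    return out
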