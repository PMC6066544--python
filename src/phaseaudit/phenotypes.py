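"""Core data container for two-phase phenotype tables.

A :class:`PhenotypeTable` holds one row per individual, a binary
environment/phase label, optional strain and stadium factors, and named
continuous trait columns.  Every trait carries a :class:`TraitMeta`
annotation stating which phenotypic *domain* it belongs to (behavioral,
morphometric, or hybrid, the latter for behavioral traits divided by a
body-size measure) and on which *timescale* it responds to a change in
rearing density (fast = hours, slow = a molt or more).

The domain/timescale annotation is load-bearing: phase transformation
decouples behavior from morphology, so downstream model audits must be able
to tell whether a predictor set mixes traits with different response times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DOMAINS = frozenset({"behavioral", "morphometric", "hybrid"})
TIMESCALES = frozenset({"fast", "slow"})


class PhenotypeError(ValueError):
    """Invalid phenotype table or model specification."""


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait annotation: phenotypic domain and response timescale."""

    domain: str
    timescale: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise PhenotypeError(
                f"unknown trait domain {self.domain!r}; expected one of {sorted(DOMAINS)}"
            )
        if self.timescale not in TIMESCALES:
            raise PhenotypeError(
                f"unknown trait timescale {self.timescale!r}; expected one of {sorted(TIMESCALES)}"
            )


@dataclass
class PhenotypeTable:
    """Individuals x {environment, optional strain/stadium, annotated traits}.

    Parameters
    ----------
    data
        One row per individual.  Must contain the ``environment`` column and
        every trait named in ``trait_meta``.
    environment
        Name of the binary phase/environment column (e.g. ``"phase"``).
    trait_meta
        Mapping trait name -> :class:`TraitMeta`.  Defines which columns are
        traits; any other column is treated as a factor or identifier.
    strain, stadium
        Optional names of categorical factor columns.
    """

    data: pd.DataFrame
    environment: str
    trait_meta: Mapping[str, TraitMeta] = field(default_factory=dict)
    strain: str | None = None
    stadium: str | None = None

    def __post_init__(self) -> None:
        if self.environment not in self.data.columns:
            raise PhenotypeError(f"environment column {self.environment!r} not in table")
        for col in (self.strain, self.stadium):
            if col is not None and col not in self.data.columns:
                raise PhenotypeError(f"factor column {col!r} not in table")
        missing = [t for t in self.trait_meta if t not in self.data.columns]
        if missing:
            raise PhenotypeError(f"trait(s) in metadata but not in table: {missing}")
        unmapped = [
            c
            for c in self.data.columns
            if c not in self.trait_meta
            and c not in {self.environment, self.strain, self.stadium}
            and pd.api.types.is_float_dtype(self.data[c])
        ]
        # float columns without metadata are allowed but traits require it;
        # model specs check again at fit time.
        self._unmapped_float_columns = unmapped

    @property
    def traits(self) -> list[str]:
        return list(self.trait_meta)

    @property
    def n(self) -> int:
        return len(self.data)

    def environment_levels(self) -> list[str]:
        levels = sorted(pd.unique(self.data[self.environment].astype(str)))
        return levels

    def require_binary_environment(self) -> tuple[str, str]:
        """Return the two sorted environment levels, or raise."""
        levels = self.environment_levels()
        if len(levels) != 2:
            raise PhenotypeError(
                f"environment column {self.environment!r} has {len(levels)} level(s) "
                f"{levels}; exactly 2 required"
            )
        return levels[0], levels[1]

    def domain_of(self, trait: str) -> str:
        try:
            return self.trait_meta[trait].domain
        except KeyError:
            raise PhenotypeError(f"trait {trait!r} has no metadata annotation") from None

    def complete_cases(self, columns: Iterable[str]) -> tuple["PhenotypeTable", int]:
        """Drop rows with missing/non-finite values in ``columns``.

        Returns the filtered table and the number of rows dropped.
        """
        cols = list(columns)
        for c in cols:
            if c not in self.data.columns:
                raise PhenotypeError(f"column {c!r} not in table")
        mask = np.ones(len(self.data), dtype=bool)
        for c in cols:
            col = self.data[c]
            if pd.api.types.is_numeric_dtype(col):
                mask &= np.isfinite(col.to_numpy(dtype=float, na_value=np.nan))
            else:
                mask &= col.notna().to_numpy()
        dropped = int((~mask).sum())
        if dropped == 0:
            return self, 0
        out = replace(self, data=self.data.loc[mask].reset_index(drop=True))
        return out, dropped

    def with_columns(self, new: pd.DataFrame, meta: Mapping[str, TraitMeta]) -> "PhenotypeTable":
        """Return a copy with additional trait columns and their metadata."""
        data = self.data.copy()
        for c in new.columns:
            data[c] = new[c].to_numpy()
        merged = dict(self.trait_meta)
        merged.update(meta)
        return replace(self, data=data, trait_meta=merged)
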