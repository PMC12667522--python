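"""Core containers shared across the pipeline.

The pipeline moves three kinds of tabular data around: non-negative
intensity matrices (proteins or phosphosites by samples), phosphosite
records with their anchoring metadata, and kinase-substrate relation
tables.  Each container wraps a :class:`pandas.DataFrame` and validates
the invariants the downstream statistics rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phosphodyn")

VALID_RESIDUES = ("S", "T", "Y")

#: metadata columns of a phosphosite table, in canonical order
SITE_META_COLUMNS = ["site_id", "protein_id", "residue", "position", "loc_prob"]


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or has a malformed layout."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent or out of range."""


@dataclass(frozen=True)
class SampleDesign:
    """Ordered assignment of samples to experimental groups (stages).

    Parameters
    ----------
    stages
        Ordered stage labels, e.g. ``("step1-2", "step3-4", "step5-6",
        "step13-14")`` for the four spermiogenesis windows.  Order is
        meaningful: trajectories and fold-change directions follow it.
    samples
        Ordered sample (channel) identifiers.
    stage_of
        Mapping from each sample id to its stage label.
    """

    stages: tuple[str, ...]
    samples: tuple[str, ...]
    stage_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValidationError("a design needs at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError("duplicate stage labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        for s in self.samples:
            if s not in self.stage_of:
                raise ValidationError(f"sample {s!r} has no stage assignment")
            if self.stage_of[s] not in self.stages:
                raise ValidationError(
                    f"sample {s!r} maps to unknown stage {self.stage_of[s]!r}"
                )
        for g in self.stages:
            n = len(self.samples_in(g))
            if n < 2:
                raise ValidationError(
                    f"stage {g!r} has {n} replicate(s); >=2 required for "
                    "variance estimation"
                )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def is_two_group(self) -> bool:
        return len(self.stages) == 2

    def samples_in(self, stage: str) -> list[str]:
        return [s for s in self.samples if self.stage_of[s] == stage]

    @classmethod
    def from_layout(cls, stages: list[str], n_replicates: int) -> "SampleDesign":
        """Build a balanced design with samples named ``<stage>.R<i>``."""
        samples = []
        stage_of = {}
        for g in stages:
            for r in range(1, n_replicates + 1):
                sid = f"{g}.R{r}"
                samples.append(sid)
                stage_of[sid] = g
        return cls(tuple(stages), tuple(samples), stage_of)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        """Read a two-column (sample, stage) design table."""
        if not {"sample", "stage"}.issubset(frame.columns):
            raise SchemaError("design table needs 'sample' and 'stage' columns")
        samples = tuple(frame["sample"].astype(str))
        stage_of = dict(zip(samples, frame["stage"].astype(str)))
        stages = tuple(pd.unique(frame["stage"].astype(str)))
        return cls(stages, samples, stage_of)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.samples),
             "stage": [self.stage_of[s] for s in self.samples]}
        )


@dataclass
class QuantMatrix:
    """Features-by-samples intensity matrix tied to a :class:`SampleDesign`.

    Values are raw (or normalized) MS intensities; negatives are invalid,
    zeros are legal and handled explicitly by the normalization rules.
    """

    values: pd.DataFrame
    design: SampleDesign
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dups)[:5]}")
        missing = [s for s in self.design.samples if s not in self.values.columns]
        if missing:
            raise SchemaError(f"missing sample columns: {missing}")
        self.values = self.values[list(self.design.samples)].astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative intensities are not allowed")

    @property
    def n_features(self) -> int:
        return len(self.values)

    def copy_with(self, values: pd.DataFrame) -> "QuantMatrix":
        return QuantMatrix(values, self.design, self.meta)


@dataclass
class PhosphoSites:
    """Phosphosite records plus their per-sample intensities.

    ``records`` carries one row per localized site with columns
    ``site_id, protein_id, residue, position, loc_prob`` (and optionally a
    precomputed centered ``window``), followed by one intensity column per
    sample in the design.
    """

    records: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        missing = [c for c in SITE_META_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"site table missing columns: {missing}")
        missing = [s for s in self.design.samples if s not in self.records.columns]
        if missing:
            raise SchemaError(f"site table missing sample columns: {missing}")
        recs = self.records
        if recs["site_id"].duplicated().any():
            dups = recs.loc[recs["site_id"].duplicated(), "site_id"]
            raise ValidationError(f"duplicate site ids: {list(dups)[:5]}")
        bad = set(recs["residue"].unique()) - set(VALID_RESIDUES)
        if bad:
            raise ValidationError(f"invalid phosphoresidues {sorted(bad)}; "
                                  f"expected one of {VALID_RESIDUES}")
        probs = recs["loc_prob"].to_numpy(dtype=float)
        if ((probs < 0) | (probs > 1)).any():
            raise ValidationError("localization probabilities must lie in [0, 1]")
        if (recs[list(self.design.samples)].to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative site intensities are not allowed")
        self.records = recs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def intensities(self) -> pd.DataFrame:
        """Site-by-sample intensity matrix indexed by site id."""
        out = self.records.set_index("site_id")[list(self.design.samples)]
        return out.astype(float)

    @property
    def site_keys(self) -> pd.Series:
        """Canonical ``protein_position_residue`` keys used to resolve KSR rows."""
        r = self.records
        return (r["protein_id"].astype(str) + "_"
                + r["residue"].astype(str)
                + r["position"].astype(int).astype(str))

    def subset(self, mask) -> "PhosphoSites":
        return PhosphoSites(self.records.loc[mask].reset_index(drop=True),
                            self.design)


def site_key(protein_id: str, residue: str, position: int) -> str:
    return f"{protein_id}_{residue}{int(position)}"


@dataclass
class KSRTable:
    """Kinase-substrate relations (e.g. exported from a GPS 5.0 run).

    One row per (kinase, substrate site) edge; substrate sites are keyed by
    protein id, residue and position, with an optional confidence tier.
    """

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["kinase", "protein_id", "residue", "position", "tier"])
    )

    def __post_init__(self) -> None:
        required = {"kinase", "protein_id", "residue", "position"}
        missing = required - set(self.edges.columns)
        if missing:
            raise SchemaError(f"KSR table missing columns: {sorted(missing)}")
        if "tier" not in self.edges.columns:
            self.edges = self.edges.assign(tier="unspecified")
        if len(self.edges) == 0:
            logger.warning("KSR table is empty; kinase enrichment will be empty")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def site_keys(self) -> pd.Series:
        e = self.edges
        return (e["protein_id"].astype(str) + "_"
                + e["residue"].astype(str)
                + e["position"].astype(int).astype(str))

    def substrates_by_kinase(self, universe: set[str] | None = None
                             ) -> dict[str, set[str]]:
        """Map kinase -> set of resolved substrate site keys.

        When ``universe`` is given, edges whose site key is not in it are
        dropped (counted and logged, never fatal), matching how predictor
        exports routinely contain sites absent from a given experiment.
        """
        keys = self.site_keys
        kin = self.edges["kinase"].astype(str)
        out: dict[str, set[str]] = {}
        unresolved = 0
        for k, s in zip(kin, keys):
            if universe is not None and s not in universe:
                unresolved += 1
                continue
            out.setdefault(k, set()).add(s)
        if unresolved:
            logger.info("KSR: %d of %d edges unresolved against the site table",
                        unresolved, len(self.edges))
        return out
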