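"""Reading, validating, and sign-coding the effect-size table.

The table has one row per extracted correlation.  Each row carries exactly
one raw payload (a reported r, a two-group test statistic, two group
summaries, or a 2×2 frequency table), the total number of animals tested,
the chooser's sex, the state factor examined, moderator codes, and the
direction metadata used to orient the correlation.

Sign convention: a coded correlation is positive exactly when choosier
individuals are the ones predicted to have high residual reproductive value
— young, attractive, large, in good condition, mated, or carrying few
parasites.  ``high_state_direction`` records whether the raw statistic's
positive pole already points that way (``as_predicted``) or must be flipped
(``reversed``).

Nonsignificant results reported without a direction ("directionless" points)
are coded as Zr = 0 in the *full* dataset variant and dropped from the
*reduced* variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import pandas as pd

from . import effect_sizes as es
from .phylogeny import PhyloCorrelation, PhyloTree, brownian_correlation, \
    grafen_calibrate, normalize_label, prune

logger = logging.getLogger("matemeta.data_io")

__all__ = [
    "EffectSizeRecord",
    "CodedEffect",
    "Dataset",
    "SchemaError",
    "RecordValidationError",
    "SEXES",
    "STATE_FACTORS",
    "STATE_VARIATION",
    "COURTER_INTERACTION",
    "DATA_TYPES",
    "DIRECTIONS",
    "CSV_COLUMNS",
    "load_table",
    "write_table",
    "code_direction",
    "code_effect",
    "apply_directionless_policy",
    "build_dataset",
]

SEXES = frozenset({"female", "male"})
STATE_FACTORS = frozenset({
    "age", "attractiveness", "body_size", "condition",
    "mating_status", "parasite_load",
})
STATE_VARIATION = frozenset({"natural", "manipulated"})
COURTER_INTERACTION = frozenset({"physical", "behavioral_only", "no_live_mate"})
DATA_TYPES = frozenset({"correlation", "group_test", "group_means", "frequency"})
DIRECTIONS = frozenset({"as_predicted", "reversed"})

SCHEMA_VERSION = "1"

# One flat row per effect; exactly one payload column-group is non-null,
# selected by data_type.
CSV_COLUMNS = [
    "record_id", "study_id", "species", "sex", "state_factor",
    "taxonomic_group", "state_variation", "courter_interaction", "data_type",
    "publication_year", "n_total", "high_state_direction", "directionless",
    "r_reported",                                    # correlation
    "stat_kind", "stat_value", "stat_df",            # group_test (+ n_1, n_2)
    "mean_1", "sd_1", "mean_2", "sd_2",              # group_means (+ n_1, n_2)
    "n_1", "n_2",
    "f_a", "f_b", "f_c", "f_d",                      # frequency
]

_PAYLOAD_GROUPS = {
    "correlation": ["r_reported"],
    "group_test": ["stat_kind", "stat_value", "stat_df", "n_1", "n_2"],
    "group_means": ["mean_1", "sd_1", "mean_2", "sd_2", "n_1", "n_2"],
    "frequency": ["f_a", "f_b", "f_c", "f_d"],
}


class SchemaError(ValueError):
    """The file as a whole does not match the documented schema."""


class RecordValidationError(ValueError):
    """A single row violates a record-level invariant."""


@dataclass(frozen=True)
class EffectSizeRecord:
    """One extracted correlation with its provenance and raw payload."""

    record_id: str
    study_id: str
    species: str
    sex: str
    state_factor: str
    taxonomic_group: str
    state_variation: str
    courter_interaction: str
    data_type: str
    publication_year: int
    n_total: int
    high_state_direction: str
    directionless: bool
    payload: object

    def __post_init__(self) -> None:
        rid = self.record_id
        if self.n_total < 4:
            raise RecordValidationError(
                f"record {rid}: n_total must be >= 4 (1/(n-3) undefined), "
                f"got {self.n_total}"
            )
        for name, value, allowed in (
            ("sex", self.sex, SEXES),
            ("state_factor", self.state_factor, STATE_FACTORS),
            ("state_variation", self.state_variation, STATE_VARIATION),
            ("courter_interaction", self.courter_interaction, COURTER_INTERACTION),
            ("data_type", self.data_type, DATA_TYPES),
            ("high_state_direction", self.high_state_direction, DIRECTIONS),
        ):
            if value not in allowed:
                raise RecordValidationError(
                    f"record {rid}: {name}={value!r} not in {sorted(allowed)}"
                )
        expected = {
            "correlation": es.RawCorrelation,
            "group_test": es.GroupTestStat,
            "group_means": es.GroupSummary,
            "frequency": es.FreqTable,
        }[self.data_type]
        if not isinstance(self.payload, expected):
            raise RecordValidationError(
                f"record {rid}: data_type {self.data_type} needs a "
                f"{expected.__name__} payload, got {type(self.payload).__name__}"
            )
        if isinstance(self.payload, (es.GroupSummary, es.GroupTestStat)):
            if self.payload.n_1 + self.payload.n_2 != self.n_total:
                raise RecordValidationError(
                    f"record {rid}: n_1 + n_2 must equal n_total"
                )
        if isinstance(self.payload, es.FreqTable) and self.payload.n != self.n_total:
            raise RecordValidationError(
                f"record {rid}: 2x2 counts must sum to n_total"
            )


@dataclass(frozen=True)
class CodedEffect:
    """A sign-coded Fisher-Z effect with its sampling variance and moderators."""

    record_id: str
    study_id: str
    species: str
    sex: str
    state_factor: str
    taxonomic_group: str
    state_variation: str
    courter_interaction: str
    data_type: str
    publication_year: int
    n_total: int
    directionless: bool
    zr: float
    v: float
    r: float


def code_direction(record: EffectSizeRecord, raw_r: float) -> float:
    """Orient a raw correlation onto the common sign convention.

    Returns +raw_r when the raw statistic's positive direction already points
    toward the "high state choosier" pole, and -raw_r when it is reversed.
    """
    if record.directionless:
        raise RecordValidationError(
            f"record {record.record_id}: directionless records carry no sign"
        )
    if abs(raw_r) >= 1.0:
        raise ValueError(f"|raw_r| must be < 1, got {raw_r}")
    return raw_r if record.high_state_direction == "as_predicted" else -raw_r


def code_effect(record: EffectSizeRecord) -> CodedEffect:
    """Convert one record to a coded Fisher-Z effect."""
    v = es.zr_variance(record.n_total)
    if record.directionless:
        zr, r = 0.0, 0.0
    else:
        raw_r = es.payload_to_r(record.payload)
        if abs(raw_r) >= 1.0:  # only reachable via reported r exactly ±1
            raw_r = math.copysign(es.R_CLAMP, raw_r)
            logger.warning("record %s: correlation at ±1 clamped to ±%s",
                           record.record_id, es.R_CLAMP)
        r = code_direction(record, raw_r)
        zr = es.fisher_z(r)
    carried = {
        f.name: getattr(record, f.name)
        for f in fields(CodedEffect)
        if f.name not in ("zr", "v", "r")
    }
    return CodedEffect(zr=zr, v=v, r=r, **carried)


def apply_directionless_policy(records, variant: str = "full"):
    """Code all records, retaining or dropping directionless points.

    ``variant="full"`` keeps directionless records at Zr = 0 with their true
    1/(n-3) variance; ``variant="reduced"`` drops them.
    """
    if variant not in ("full", "reduced"):
        raise ValueError(f"variant must be 'full' or 'reduced', got {variant!r}")
    coded = [code_effect(rec) for rec in records]
    if variant == "reduced":
        kept = [c for c in coded if not c.directionless]
    else:
        kept = coded
    logger.info("directionless policy (%s): %d retained, %d dropped",
                variant, len(kept), len(coded) - len(kept))
    return kept


# ---------------------------------------------------------------------------
# CSV reading / writing

def _build_payload(row: pd.Series, data_type: str):
    group = _PAYLOAD_GROUPS[data_type]
    missing = [c for c in group if pd.isna(row[c])]
    if missing:
        raise RecordValidationError(
            f"data_type {data_type} requires columns {group}; missing {missing}"
        )
    others = [
        c for g, cols in _PAYLOAD_GROUPS.items() if g != data_type
        for c in cols if c not in group and not pd.isna(row[c])
    ]
    if others:
        raise RecordValidationError(
            f"exactly one payload group may be filled; extra values in {others}"
        )
    if data_type == "correlation":
        return es.RawCorrelation(float(row["r_reported"]))
    if data_type == "group_test":
        return es.GroupTestStat(str(row["stat_kind"]), float(row["stat_value"]),
                                float(row["stat_df"]), int(row["n_1"]),
                                int(row["n_2"]))
    if data_type == "group_means":
        return es.GroupSummary(float(row["mean_1"]), float(row["sd_1"]),
                               int(row["n_1"]), float(row["mean_2"]),
                               float(row["sd_2"]), int(row["n_2"]))
    return es.FreqTable(int(row["f_a"]), int(row["f_b"]),
                        int(row["f_c"]), int(row["f_d"]))


def load_table(path, schema_version: str = SCHEMA_VERSION):
    """Load and validate an effect-size CSV.

    Returns ``(records, rejects)`` where ``rejects`` is a list of
    ``(row_number, record_id, message)`` for rows failing record-level
    validation (1-based row numbers, excluding the header).  A missing
    mandatory column is a file-level :class:`SchemaError`.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    records, rejects = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = pd.Series(row._asdict())
        rid = str(row["record_id"])
        try:
            data_type = str(row["data_type"])
            if data_type not in DATA_TYPES:
                raise RecordValidationError(
                    f"record {rid}: unknown data_type {data_type!r}")
            payload = _build_payload(row, data_type)
            rec = EffectSizeRecord(
                record_id=rid,
                study_id=str(row["study_id"]),
                species=str(row["species"]),
                sex=str(row["sex"]),
                state_factor=str(row["state_factor"]),
                taxonomic_group=str(row["taxonomic_group"]),
                state_variation=str(row["state_variation"]),
                courter_interaction=str(row["courter_interaction"]),
                data_type=data_type,
                publication_year=int(row["publication_year"]),
                n_total=int(row["n_total"]),
                high_state_direction=str(row["high_state_direction"]),
                directionless=_parse_bool(row["directionless"]),
                payload=payload,
            )
        except (RecordValidationError, ValueError, TypeError) as exc:
            rejects.append((i, rid, str(exc)))
            logger.warning("row %d (record %s) rejected: %s", i, rid, exc)
            continue
        records.append(rec)
    logger.info("loaded %d records, rejected %d rows", len(records), len(rejects))
    return records, rejects


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().casefold()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise RecordValidationError(f"cannot parse boolean {x!r}")


def write_table(records, path) -> None:
    """Write records to the CSV schema (inverse of :func:`load_table`)."""
    rows = []
    for rec in records:
        row = {c: None for c in CSV_COLUMNS}
        for name in ("record_id", "study_id", "species", "sex", "state_factor",
                     "taxonomic_group", "state_variation", "courter_interaction",
                     "data_type", "publication_year", "n_total",
                     "high_state_direction", "directionless"):
            row[name] = getattr(rec, name)
        p = rec.payload
        if isinstance(p, es.RawCorrelation):
            row["r_reported"] = p.r_reported
        elif isinstance(p, es.GroupTestStat):
            row.update(stat_kind=p.statistic_kind, stat_value=p.value,
                       stat_df=p.df, n_1=p.n_1, n_2=p.n_2)
        elif isinstance(p, es.GroupSummary):
            row.update(mean_1=p.mean_1, sd_1=p.sd_1, mean_2=p.mean_2,
                       sd_2=p.sd_2, n_1=p.n_1, n_2=p.n_2)
        elif isinstance(p, es.FreqTable):
            row.update(f_a=p.a, f_b=p.b, f_c=p.c, f_d=p.d)
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset assembly

@dataclass
class Dataset:
    """Coded effects paired with the (pruned, calibrated) species tree."""

    effects: list
    tree: PhyloTree | None
    variant: str
    correlation: PhyloCorrelation | None = None

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.effects:
            seen.setdefault(normalize_label(e.species), None)
        return list(seen)

    def filter(self, predicate) -> "Dataset":
        """Dataset restricted to effects satisfying ``predicate`` (tree re-pruned)."""
        kept_records = [e for e in self.effects if predicate(e)]
        return _assemble(kept_records, self.tree, self.variant)


def build_dataset(records, tree: PhyloTree, variant: str = "full",
                  sex: str | None = None, recalibrate: bool = True) -> Dataset:
    """Code records, apply the directionless policy, and pair with the tree.

    The tree is pruned to the species present (recalibrated by default) and
    its Brownian correlation matrix is attached.  Raises if any species in
    the data is missing from the tree.
    """
    if sex is not None:
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}")
        records = [r for r in records if r.sex == sex]
    coded = apply_directionless_policy(records, variant)
    return _assemble(coded, tree, variant, recalibrate=recalibrate)


def _assemble(coded, tree, variant, recalibrate: bool = True) -> Dataset:
    if not coded:
        raise ValueError("no effects left after filtering")
    if tree is None:
        return Dataset(coded, None, variant, None)
    tips = set(tree.normalized_tip_labels)
    species = {normalize_label(e.species) for e in coded}
    missing = sorted(species - tips)
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    if len(species) >= 2:
        sub = prune(tree, species, recalibrate=recalibrate)
        if not sub.calibrated:
            sub = grafen_calibrate(sub)
        corr = brownian_correlation(sub)
    else:
        import numpy as np
        only = tree.normalized_tip_labels[next(iter(species))]
        sub = tree
        corr = PhyloCorrelation([only], np.eye(1))
    return Dataset(coded, sub, variant, corr)
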