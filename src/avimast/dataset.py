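"""Record-level survey data: validation, species aggregation, PIR screen.

One row per observation report (a literature account, an expert
questionnaire response, or a citizen-science report) of whether a bird of a
given species was observed masturbating, together with categorical
covariates (sex, age, wild/captive origin, housing, rearing, condition) and
species-level mating-system flags.  A species is classed as exhibiting the
behaviour if a single record confirms it; state frequencies over records
carry intraspecific variation into the tree-based analyses.

The phylogenetic imbalance ratio (PIR) screens whether the trait's
distribution over the tree carries enough information for comparative model
fitting (Gardner & Organ's adequacy statistic: values in [0, 1], lower
better, < 0.1 suggested adequate).  This module computes a likelihood-ratio
operationalisation of that screen: the ratio of the best phylogeny-free
(iid Bernoulli) likelihood of the presence/absence vector to the best
two-state ARD Mk likelihood on the tree, clipped to [0, 1].  A trait whose
distribution is strongly structured by the phylogeny makes the tree model
far better than the iid model and drives the ratio toward 0; a monomorphic
trait carries no information and returns 1 with a warning.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ctmc
from .treeio import Phylogeny, normalize_label

log = logging.getLogger(__name__)

YESNO = ("yes", "no")
SEX_LEVELS = ("male", "female", "unknown")
AGE_LEVELS = ("adult", "juvenile", "unknown")
ORIGIN_LEVELS = ("wild", "captive")
SOCIAL_ENV_LEVELS = ("mixed-species", "solitary", "opposite-sex",
                     "same-sex", "unknown")
REARING_LEVELS = ("parent", "hand", "unknown")
CONDITION_LEVELS = ("good", "poor", "unknown")
SOURCE_LEVELS = ("literature", "expert", "citizen")
FLAG_COLUMNS = ("social_monogamy", "long_term_pair_bond", "lekking",
                "multiple_mates", "cooperative_breeding")

MANDATORY_COLUMNS = ("species", "masturbation", "sex", "age", "origin",
                     "social_env", "rearing", "condition", "n_observed",
                     "source")


class SchemaError(ValueError):
    pass


class RecordValidationError(ValueError):
    """Carries (line_number, message) pairs for every offending row."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        msg = "; ".join(f"line {ln}: {m}" for ln, m in problems[:10])
        if len(problems) > 10:
            msg += f" (+{len(problems) - 10} more)"
        super().__init__(msg)


@dataclass
class ObservationRecord:
    """One observation report."""

    species: str
    masturbation: str            # yes/no
    sex: str = "unknown"
    age: str = "unknown"
    origin: str = "captive"
    social_env: str = "unknown"
    rearing: str = "unknown"     # meaningful only when origin == captive
    condition: str = "unknown"
    n_observed: int = 1
    source: str = "expert"
    flags: dict[str, str] = field(default_factory=dict)  # mating-system y/n

    def validate(self) -> list[str]:
        errs = []
        if not str(self.species).strip():
            errs.append("species is empty")
        checks = [("masturbation", self.masturbation, YESNO),
                  ("sex", self.sex, SEX_LEVELS),
                  ("age", self.age, AGE_LEVELS),
                  ("origin", self.origin, ORIGIN_LEVELS),
                  ("social_env", self.social_env, SOCIAL_ENV_LEVELS),
                  ("rearing", self.rearing, REARING_LEVELS),
                  ("condition", self.condition, CONDITION_LEVELS),
                  ("source", self.source, SOURCE_LEVELS)]
        for name, value, levels in checks:
            if str(value).strip().lower() not in levels:
                errs.append(f"{name}={value!r} not in {levels}")
        if self.origin == "wild" and self.rearing not in ("unknown", ""):
            errs.append("rearing only applies to captive records")
        try:
            if int(self.n_observed) < 1:
                errs.append("n_observed must be a positive integer")
        except (TypeError, ValueError):
            errs.append(f"n_observed={self.n_observed!r} is not an integer")
        for k, v in self.flags.items():
            if k not in FLAG_COLUMNS:
                errs.append(f"unknown flag column {k!r}")
            elif str(v).strip().lower() not in ("y", "n", "yes", "no", ""):
                errs.append(f"{k}={v!r} must be y/n")
        return errs


def _norm(v) -> str:
    return str(v).strip().lower()


def load_records(path_or_buffer, delimiter: str | None = None
                 ) -> list[ObservationRecord]:
    """Read and validate a delimited record file (CSV default, TSV by
    sniffing or explicit delimiter).

    Raises :class:`SchemaError` for missing mandatory columns or an empty
    file, and :class:`RecordValidationError` listing the 1-based line number
    of every row failing an enumeration check.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer, "r", encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        raise SchemaError("empty record file")
    if delimiter is None:
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    header = [h.strip().lower() for h in reader.fieldnames or []]
    missing = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    records: list[ObservationRecord] = []
    problems: list[tuple[int, str]] = []
    for ln, row in enumerate(reader, start=2):  # header is line 1
        row = {(k or "").strip().lower(): (v or "") for k, v in row.items()}
        flags = {c: _norm(row[c]) for c in FLAG_COLUMNS if c in row}
        rec = ObservationRecord(
            species=row["species"].strip(),
            masturbation=_norm(row["masturbation"]),
            sex=_norm(row["sex"]) or "unknown",
            age=_norm(row["age"]) or "unknown",
            origin=_norm(row["origin"]),
            social_env=_norm(row["social_env"]) or "unknown",
            rearing=_norm(row["rearing"]) or "unknown",
            condition=_norm(row["condition"]) or "unknown",
            n_observed=row["n_observed"] or 1,
            source=_norm(row["source"]),
            flags=flags)
        errs = rec.validate()
        if errs:
            problems.extend((ln, e) for e in errs)
        else:
            rec.n_observed = int(rec.n_observed)
            records.append(rec)
    if problems:
        raise RecordValidationError(problems)
    if not records:
        raise SchemaError("no data rows")
    return records


def records_to_frame(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in dc_fields(r)
             if f.name != "flags"}
        for c in FLAG_COLUMNS:
            d[c] = r.flags.get(c, "")
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(records: Sequence[ObservationRecord] | pd.DataFrame,
                  path) -> None:
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_frame(records))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Species-level aggregation
# ---------------------------------------------------------------------------

def aggregate_species(records: Sequence[ObservationRecord] | pd.DataFrame
                      ) -> pd.DataFrame:
    """Species trait table.

    One row per species: ``record_count``, ``count_yes``, ``count_no``,
    ``presence`` (true iff a single record confirms the behaviour) and the
    record state frequencies ``freq_absent``/``freq_present``.  Each row of
    the input counts once regardless of ``n_observed`` (proportions are over
    records, matching how the survey data are summarised).  Aggregation is
    order-invariant and idempotent.
    """
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_frame(records))
    if df.empty:
        raise SchemaError("no records to aggregate")
    key = df["species"].map(normalize_label)
    yes = df["masturbation"].map(_norm).eq("yes").astype(int)
    out = (pd.DataFrame({"species": key, "yes": yes, "name": df["species"]})
           .groupby("species", sort=True)
           .agg(record_count=("yes", "size"), count_yes=("yes", "sum"),
                name=("name", "first")))
    out["count_no"] = out["record_count"] - out["count_yes"]
    out["presence"] = out["count_yes"] >= 1
    out["freq_present"] = out["count_yes"] / out["record_count"]
    out["freq_absent"] = 1.0 - out["freq_present"]
    return out


def species_presence(table: pd.DataFrame) -> dict[str, bool]:
    return {sp: bool(p) for sp, p in table["presence"].items()}


def state_frequency_priors(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Tip priors carrying intraspecific variation (record frequencies)."""
    return {sp: np.array([row["freq_absent"], row["freq_present"]])
            for sp, row in table.iterrows()}


def species_flags(records: Sequence[ObservationRecord] | pd.DataFrame
                  ) -> pd.DataFrame:
    """Per-species mating-system flags (y/n), first non-empty value wins.

    Warns when ``long_term_pair_bond`` is set for a species not flagged as
    socially monogamous (the flag is only meaningful under monogamy).
    """
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_frame(records))
    cols = [c for c in FLAG_COLUMNS if c in df.columns]
    key = df["species"].map(normalize_label)
    agg = {}
    for c in cols:
        vals = df[c].map(_norm).replace({"yes": "y", "no": "n", "": np.nan})
        agg[c] = vals.groupby(key).first()
    out = pd.DataFrame(agg)
    if {"social_monogamy", "long_term_pair_bond"} <= set(out.columns):
        bad = out[(out["long_term_pair_bond"] == "y")
                  & (out["social_monogamy"] != "y")]
        if len(bad):
            warnings.warn(f"long_term_pair_bond set without social monogamy "
                          f"for: {list(bad.index)[:5]}", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Subset summaries
# ---------------------------------------------------------------------------

def subset_summary(records: Sequence[ObservationRecord] | pd.DataFrame,
                   by: str) -> pd.DataFrame:
    """Per-level record counts and proportion of records reporting the
    behaviour; levels with zero records are omitted (with a log note)."""
    df = (records if isinstance(records, pd.DataFrame)
          else records_to_frame(records))
    if by not in df.columns:
        raise SchemaError(f"unknown factor: {by!r}")
    levels = df[by].map(_norm)
    yes = df["masturbation"].map(_norm).eq("yes").astype(int)
    out = (pd.DataFrame({by: levels, "yes": yes})
           .groupby(by, sort=True)
           .agg(n_records=("yes", "size"), n_yes=("yes", "sum")))
    out["prop_yes"] = out["n_yes"] / out["n_records"]
    declared = {"sex": SEX_LEVELS, "age": AGE_LEVELS, "origin": ORIGIN_LEVELS,
                "social_env": SOCIAL_ENV_LEVELS, "rearing": REARING_LEVELS,
                "condition": CONDITION_LEVELS, "source": SOURCE_LEVELS}
    for lv in declared.get(by, ()):
        if lv not in out.index:
            log.info("level %r of %r has zero records; omitted", lv, by)
    return out


# ---------------------------------------------------------------------------
# PIR adequacy screen
# ---------------------------------------------------------------------------

def pir(presence: Mapping[str, bool] | pd.Series, tree: Phylogeny) -> float:
    """Phylogenetic imbalance ratio adequacy screen, in [0, 1], lower better.

    Computed as ``exp(ll_iid - ll_tree)`` where ``ll_iid`` is the maximised
    log-likelihood of the presence vector under an iid Bernoulli model
    (phylogeny-free) and ``ll_tree`` the maximised log-likelihood under the
    two-state ARD Mk model on the tree, clipped to [0, 1].  Values below
    ~0.1 mean the phylogeny improves the fit by more than two nats --
    enough trait-tree structure for comparative parameter estimation to be
    feasible.  Deterministic: the ML fit uses a fixed start grid.

    A monomorphic trait (all species in one state) yields 1.0 with a
    warning: such data carry no information about trait evolution.
    """
    if isinstance(presence, pd.Series):
        presence = {str(k): bool(v) for k, v in presence.items()}
    if not presence:
        raise SchemaError("empty presence vector")
    labels = {normalize_label(lb) for lb in tree.tip_labels}
    missing = [s for s in presence if normalize_label(s) not in labels]
    if missing:
        raise SchemaError(f"species with presence data not in tree: "
                          f"{missing[:5]}")
    sub = tree
    if len(presence) < tree.n_tips:
        sub = tree.prune_to(presence.keys())
    vals = np.array([bool(v) for v in presence.values()])
    n1 = int(vals.sum())
    n0 = vals.size - n1
    if n0 == 0 or n1 == 0:
        warnings.warn("monomorphic trait: PIR is uninformative (1.0)",
                      stacklevel=2)
        return 1.0
    p1 = n1 / vals.size
    ll_iid = n1 * np.log(p1) + n0 * np.log(1.0 - p1)
    priors = ctmc.presence_priors(dict(presence))
    fit = ctmc.fit_ard(sub, priors)
    diff = ll_iid - fit.loglik
    if diff >= 0:  # phylogeny adds nothing: least adequate
        return 1.0
    return float(np.exp(max(diff, -745.0)))
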