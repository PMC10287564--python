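"""ICD-10 endpoint curation and first-event survival extraction.

Endpoints are named sets of three-character ICD-10 codes with a chapter and
a WHO-alcohol-related flag. Curation keeps endpoints with at least 80 first
events among current drinkers (sex-specific), pools the remaining codes of
each chapter into a "less-common" endpoint, and drops chapters that are not
relevant to the analyzed sex (perinatal XVI and congenital XVII always;
pregnancy-related XV in men). Survival extraction applies the 35-84
age-at-risk window with censoring at death from any cause (cause-specific
hazards).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataIntegrityError

__all__ = [
    "EndpointDefinition",
    "EndpointCatalog",
    "chapter_of",
    "curate_endpoint_catalog",
    "extract_first_events",
    "aggregate_endpoint",
    "AGE_WINDOW",
]

#: Default age-at-risk window (entry at 35, truncation at 85).
AGE_WINDOW = (35.0, 85.0)

# ICD-10 chapter boundaries: (first code, last code, chapter numeral).
_CHAPTER_RANGES = [
    ("A00", "B99", "I"), ("C00", "D48", "II"), ("D50", "D89", "III"),
    ("E00", "E90", "IV"), ("F00", "F99", "V"), ("G00", "G99", "VI"),
    ("H00", "H59", "VII"), ("H60", "H95", "VIII"), ("I00", "I99", "IX"),
    ("J00", "J99", "X"), ("K00", "K93", "XI"), ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"), ("N00", "N99", "XIV"), ("O00", "O99", "XV"),
    ("P00", "P96", "XVI"), ("Q00", "Q99", "XVII"), ("R00", "R99", "XVIII"),
    ("S00", "T98", "XIX"), ("V01", "Y98", "XX"),
]

EXCLUDED_CHAPTERS = ("XVI", "XVII")
MALE_EXCLUDED_CHAPTERS = ("XV", "XVI", "XVII")


def chapter_of(code: str) -> str:
    """ICD-10 chapter (Roman numeral I-XX) of a three-character code."""
    code = str(code).strip().upper()
    if len(code) != 3 or not code[0].isalpha() or not code[1:].isdigit():
        raise DataIntegrityError(f"not a three-character ICD-10 code: {code!r}")
    for lo, hi, chap in _CHAPTER_RANGES:
        if lo <= code <= hi:
            return chap
    raise DataIntegrityError(f"code {code!r} outside ICD-10 chapters I-XX")


def _expand_codes(spec: str) -> tuple[str, ...]:
    """Expand a semicolon-separated code list with ranges, e.g. 'A15-A19;B90'."""
    out: list[str] = []
    for part in str(spec).split(";"):
        part = part.strip().upper()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-")
            if lo[0] == hi[0]:
                out.extend(f"{lo[0]}{i:02d}" for i in range(int(lo[1:]), int(hi[1:]) + 1))
            else:  # letter-crossing range, e.g. S00-T98 or V01-V99+W...
                letters = [chr(c) for c in range(ord(lo[0]), ord(hi[0]) + 1)]
                for li, letter in enumerate(letters):
                    start = int(lo[1:]) if li == 0 else 0
                    stop = int(hi[1:]) if li == len(letters) - 1 else 99
                    out.extend(f"{letter}{i:02d}" for i in range(start, stop + 1))
        else:
            out.append(part)
    return tuple(dict.fromkeys(out))


@dataclass(frozen=True)
class EndpointDefinition:
    """A named ICD-10 disease endpoint."""

    endpoint_id: str
    label: str
    codes: tuple[str, ...]
    chapter: str
    who_related: bool = False
    aggregates: tuple[str, ...] = ()

    @classmethod
    def from_codes(cls, endpoint_id, label, code_spec, who_related=False):
        codes = _expand_codes(code_spec)
        chapters = {chapter_of(c) for c in codes}
        chapter = min(chapters) if len(chapters) == 1 else "mixed"
        return cls(endpoint_id, label, codes, chapter, bool(who_related))


class EndpointCatalog:
    """An ordered collection of endpoint definitions with code lookup."""

    def __init__(self, endpoints: list[EndpointDefinition]):
        self.endpoints = list(endpoints)
        self._by_id = {e.endpoint_id: e for e in self.endpoints}
        if len(self._by_id) != len(self.endpoints):
            raise ConfigurationError("duplicate endpoint ids in catalog")

    def __iter__(self):
        return iter(self.endpoints)

    def __len__(self):
        return len(self.endpoints)

    def __contains__(self, endpoint_id):
        return endpoint_id in self._by_id

    def get(self, endpoint_id: str) -> EndpointDefinition:
        return self._by_id[endpoint_id]

    @property
    def ids(self) -> list[str]:
        return [e.endpoint_id for e in self.endpoints]

    def code_map(self) -> dict[str, str]:
        """Map each covered code to its endpoint id (first definition wins)."""
        out: dict[str, str] = {}
        for e in self.endpoints:
            for c in e.codes:
                out.setdefault(c, e.endpoint_id)
        return out

    @classmethod
    def from_csv(cls, path) -> "EndpointCatalog":
        df = pd.read_csv(path)
        eps = [EndpointDefinition.from_codes(r.endpoint_id, r.label, r.codes,
                                             bool(r.who_flag))
               for r in df.itertuples()]
        return cls(eps)

    @classmethod
    def default(cls) -> "EndpointCatalog":
        """The catalog shipped with the package (editable CSV)."""
        ref = importlib.resources.files("alcophewas") / "data" / "endpoints.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "endpoint_id": [e.endpoint_id for e in self.endpoints],
            "label": [e.label for e in self.endpoints],
            "codes": [";".join(e.codes) for e in self.endpoints],
            "chapter": [e.chapter for e in self.endpoints],
            "who_flag": [int(e.who_related) for e in self.endpoints],
        })


def _validate_event_codes(events: pd.DataFrame) -> pd.Series:
    codes = events["icd10"].astype(str).str.strip().str.upper()
    chapters = {}
    bad = []
    for c in codes.unique():
        try:
            chapters[c] = chapter_of(c)
        except DataIntegrityError:
            bad.append(c)
    if bad:
        raise DataIntegrityError(
            f"{len(bad)} event code(s) outside ICD-10 chapters I-XX: {sorted(bad)}")
    return codes.map(chapters)


def curate_endpoint_catalog(events: pd.DataFrame, participants: pd.DataFrame,
                            exposure: pd.DataFrame, sex: str,
                            base_catalog: EndpointCatalog | None = None,
                            min_cases: int = 80) -> EndpointCatalog:
    """Curate the endpoint catalog for one sex.

    Endpoints from ``base_catalog`` with at least ``min_cases`` distinct
    current-drinker cases (of the given sex) are retained individually;
    every other observed code falls into its chapter's pooled
    ``less_common_<chapter>`` endpoint. Chapters XVI/XVII are excluded, and
    XV as well when ``sex == "M"``. Curation is idempotent: re-running on
    the same inputs returns the same catalog.
    """
    base_catalog = base_catalog or EndpointCatalog.default()
    excluded = MALE_EXCLUDED_CHAPTERS if sex == "M" else EXCLUDED_CHAPTERS

    ev = events.copy()
    ev["chapter"] = _validate_event_codes(ev)
    ev["icd10"] = ev["icd10"].astype(str).str.strip().str.upper()
    ev = ev[~ev["chapter"].isin(excluded)]

    sex_ids = set(participants.loc[participants["sex"] == sex, "id"])
    current_ids = set(exposure.loc[exposure["status"] == "current", "id"]) & sex_ids
    ev_sex = ev[ev["id"].isin(sex_ids)]
    ev_cur = ev_sex[ev_sex["id"].isin(current_ids)]

    code_map = base_catalog.code_map()
    ep_of_event = ev_cur["icd10"].map(code_map)
    case_counts = (pd.DataFrame({"endpoint": ep_of_event, "id": ev_cur["id"]})
                   .dropna().groupby("endpoint")["id"].nunique())

    retained: list[EndpointDefinition] = []
    retained_codes: set[str] = set()
    for e in base_catalog:
        if e.chapter in excluded:
            continue
        if int(case_counts.get(e.endpoint_id, 0)) >= min_cases:
            retained.append(e)
            retained_codes.update(e.codes)

    # everything observed in this sex but not individually retained pools
    # into its chapter's less-common endpoint
    leftover = ev_sex[~ev_sex["icd10"].isin(retained_codes)]
    pools = leftover.groupby("chapter")["icd10"].unique()
    numeral_order = {c: i for i, (_, _, c) in enumerate(_CHAPTER_RANGES)}
    for chap in sorted(pools.index, key=numeral_order.get):
        codes = tuple(sorted(pools[chap]))
        retained.append(EndpointDefinition(
            endpoint_id=f"less_common_{chap}",
            label=f"Less-common conditions of chapter {chap}",
            codes=codes, chapter=chap, who_related=False))
    return EndpointCatalog(retained)


def extract_first_events(events: pd.DataFrame, endpoint: EndpointDefinition,
                         participants: pd.DataFrame,
                         window: tuple[float, float] = AGE_WINDOW) -> pd.DataFrame:
    """First-event survival dataset for one endpoint.

    Per participant: entry at max(baseline age, window start), exit at the
    first endpoint event inside the age window, else at the earliest of
    death, loss/study-end censoring or the window end (cause-specific
    censoring at death from any cause). Participants with no follow-up
    inside the window are dropped.

    Returns columns ``id``, ``entry_age``, ``exit_age``, ``event``,
    ``censor_reason`` (one of death/study-end/age-85/"." when the event
    occurred).
    """
    lo, hi = window
    p = participants
    entry = np.maximum(p["age_baseline"].to_numpy(float), lo)
    end_admin = np.minimum(p["death_age"].to_numpy(float), p["censor_age"].to_numpy(float))
    end = np.minimum(end_admin, hi)

    ev = events[events["icd10"].isin(endpoint.codes)]
    if len(ev):
        merged = ev.merge(p[["id", "age_baseline", "death_age", "censor_age"]], on="id")
        eps = 1e-9
        bad = ((merged["age"] < merged["age_baseline"] - eps)
               | (merged["age"] > np.minimum(merged["death_age"],
                                             merged["censor_age"]) + eps))
        if bad.any():
            raise DataIntegrityError(
                f"{int(bad.sum())} event(s) outside follow-up for endpoint "
                f"{endpoint.endpoint_id}")
        inside = ev[(ev["age"] >= lo) & (ev["age"] < hi)]
        first = inside.groupby("id")["age"].min()
    else:
        first = pd.Series(dtype=float)

    first_age = p["id"].map(first).to_numpy(float)
    has_event = ~np.isnan(first_age) & (first_age <= end)
    exit_age = np.where(has_event, first_age, end)
    # guard against zero-length intervals when the event lands exactly on entry
    exit_age = np.where(has_event & (exit_age <= entry), entry + 1e-9, exit_age)

    death = p["death_age"].to_numpy(float)
    censor = p["censor_age"].to_numpy(float)
    reason = np.select(
        [has_event, (death <= censor) & (death <= hi), end >= hi],
        [".", "death", "age-85"], default="study-end")

    out = pd.DataFrame({
        "id": p["id"].to_numpy(),
        "entry_age": entry,
        "exit_age": exit_age,
        "event": has_event.astype(int),
        "censor_reason": reason,
    })
    return out[out["exit_age"] > out["entry_age"]].reset_index(drop=True)


def aggregate_endpoint(members: list[EndpointDefinition], endpoint_id: str,
                       label: str) -> EndpointDefinition:
    """Aggregate endpoint: first event across member code sets.

    The survival dataset of the aggregate (via :func:`extract_first_events`)
    uses each participant's earliest event over the union of member codes.
    """
    if not members:
        raise ConfigurationError("aggregate endpoint needs at least one member")
    codes = tuple(dict.fromkeys(c for m in members for c in m.codes))
    chapters = {m.chapter for m in members}
    return EndpointDefinition(
        endpoint_id=endpoint_id, label=label, codes=codes,
        chapter=chapters.pop() if len(chapters) == 1 else "mixed",
        who_related=all(m.who_related for m in members),
        aggregates=tuple(m.endpoint_id for m in members))
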