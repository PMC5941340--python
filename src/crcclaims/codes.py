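"""ICD-9 / ICD-10 diagnostic code sets and treatment code sets for colorectal cancer.

Diagnostic codes are matched by *prefix* against normalized codes (dots stripped,
upper-cased), because ICD hierarchies nest: ``C18`` covers ``C18.0``–``C18.9``.
Treatment / billing-act codes are jurisdiction-specific and flat, so they are
matched exactly and grouped into three therapeutic families: surgery,
chemotherapy/radiotherapy, and other CRC-directed care.

The default diagnostic set is the standard CRC surveillance definition:
ICD-9 153.x (colon), 154.0 and 154.1 (rectosigmoid junction and rectum);
ICD-10 C18.x (colon), C19 (rectosigmoid junction) and C20 (rectum). Anal-canal
codes (ICD-9 154.2+, ICD-10 C21) are excluded. The default treatment codes are
an explicit placeholder taxonomy used by the simulator and tests; a real
deployment supplies its own billing-act list via :func:`load_code_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "ICDVersion",
    "Site",
    "TreatmentGroup",
    "CodeSet",
    "CodeConfigError",
    "normalize_code",
    "default_code_set",
    "load_code_config",
]


class ICDVersion(str, Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class Site(str, Enum):
    COLON = "colon"
    RECTUM = "rectum"
    UNSPECIFIED = "unspecified"


class TreatmentGroup(str, Enum):
    SURGERY = "surgery"
    CHEMO_RADIO = "chemo_radio"
    OTHER = "other"


class CodeConfigError(ValueError):
    """Raised when a code-set configuration violates its invariants."""


def normalize_code(code: str) -> str:
    """Strip dots and whitespace, upper-case. ``'c18.7' -> 'C187'``."""
    return code.replace(".", "").strip().upper()


def _check_no_nested_prefixes(prefixes: list[str], version: str) -> None:
    for i, a in enumerate(prefixes):
        for b in prefixes[i + 1 :]:
            if a.startswith(b) or b.startswith(a):
                raise CodeConfigError(
                    f"{version} prefixes {a!r} and {b!r} nest; one would double-count the other"
                )


@dataclass(frozen=True)
class CodeSet:
    """Named, validated collection of CRC diagnostic prefixes and treatment codes.

    ``site_map`` maps normalized diagnostic prefixes to a site label; any
    matching code whose prefix is absent from the map is ``unspecified``.
    """

    name: str
    icd9_prefixes: tuple[str, ...]
    icd10_prefixes: tuple[str, ...]
    treatment_codes: dict[TreatmentGroup, frozenset[str]]
    site_map: dict[str, Site] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prefixes, version in ((self.icd9_prefixes, "ICD9"), (self.icd10_prefixes, "ICD10")):
            if any(not p for p in prefixes):
                raise CodeConfigError(f"empty {version} prefix")
            _check_no_nested_prefixes(list(prefixes), version)
        seen: dict[str, TreatmentGroup] = {}
        for group, codes in self.treatment_codes.items():
            for c in codes:
                if c in seen:
                    raise CodeConfigError(
                        f"treatment code {c!r} listed in both {seen[c].value!r} and {group.value!r}"
                    )
                seen[c] = group

    # -- diagnostic matching ------------------------------------------------

    def _prefixes_for(self, version: ICDVersion | str) -> tuple[str, ...]:
        version = ICDVersion(version)
        if version is ICDVersion.ICD9:
            return self.icd9_prefixes
        return self.icd10_prefixes

    def match_dx(self, code: str, version: ICDVersion | str) -> bool:
        """True iff the normalized code starts with a prefix of this version's list."""
        if not code:
            return False
        norm = normalize_code(code)
        return any(norm.startswith(normalize_code(p)) for p in self._prefixes_for(version))

    def site_of(self, code: str, version: ICDVersion | str) -> Site:
        """Site label for a diagnostic code; ``unspecified`` for non-matching codes."""
        if not code or not self.match_dx(code, version):
            return Site.UNSPECIFIED
        norm = normalize_code(code)
        # Longest matching site prefix wins so e.g. 1540/1541 beat a broader 154 entry.
        best: tuple[int, Site] | None = None
        for prefix, site in self.site_map.items():
            p = normalize_code(prefix)
            if norm.startswith(p) and (best is None or len(p) > best[0]):
                best = (len(p), site)
        return best[1] if best is not None else Site.UNSPECIFIED

    # -- treatment matching -------------------------------------------------

    def match_treatment(self, code: str) -> TreatmentGroup | None:
        """Exact-match a billing act / intervention code; None when unlisted."""
        if not code:
            return None
        norm = normalize_code(code)
        for group, codes in self.treatment_codes.items():
            if norm in codes:
                return group
        return None


#: Placeholder treatment-act codes used by the simulator and tests. Real
#: deployments must supply jurisdictional billing acts via a config file.
_DEFAULT_TREATMENT = {
    TreatmentGroup.SURGERY: frozenset({"SURG-COLECT", "SURG-PROCT", "SURG-LAR"}),
    TreatmentGroup.CHEMO_RADIO: frozenset({"CHEMO-FU", "CHEMO-FOLFOX", "RADIO-PELV"}),
    TreatmentGroup.OTHER: frozenset({"OTH-STOMA", "OTH-PALL"}),
}

_DEFAULT_SITE_MAP = {
    "153": Site.COLON,
    "C18": Site.COLON,
    "1540": Site.RECTUM,
    "1541": Site.RECTUM,
    "C19": Site.RECTUM,
    "C20": Site.RECTUM,
}


def default_code_set() -> CodeSet:
    """Built-in CRC code set (ICD-9 153.x/154.0/154.1; ICD-10 C18/C19/C20)."""
    return CodeSet(
        name="crc-default",
        icd9_prefixes=("153", "1540", "1541"),
        icd10_prefixes=("C18", "C19", "C20"),
        treatment_codes=dict(_DEFAULT_TREATMENT),
        site_map=dict(_DEFAULT_SITE_MAP),
    )


def load_code_config(path: str | Path | None = None) -> CodeSet:
    """Load a code set from a YAML mapping; the built-in default when path is None.

    Expected keys: ``icd9``, ``icd10`` (lists of prefixes),
    ``treatment.surgery`` / ``treatment.chemo_radio`` / ``treatment.other``
    (lists of exact codes) and ``site_map`` (prefix -> colon|rectum).
    """
    if path is None:
        return default_code_set()
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise CodeConfigError(f"code config {path} is not a mapping")
    treatment = raw.get("treatment", {}) or {}
    return CodeSet(
        name=str(raw.get("name", Path(path).stem)),
        icd9_prefixes=tuple(str(p) for p in raw.get("icd9", [])),
        icd10_prefixes=tuple(str(p) for p in raw.get("icd10", [])),
        treatment_codes={
            TreatmentGroup(g): frozenset(normalize_code(str(c)) for c in treatment.get(g, []) or [])
            for g in ("surgery", "chemo_radio", "other")
        },
        site_map={str(k): Site(v) for k, v in (raw.get("site_map", {}) or {}).items()},
    )
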