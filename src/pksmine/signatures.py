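"""Motif-anchored detection and classification of type I PKS catalytic domains.

Each domain class is located by an anchor motif (regular expression over the
protein) and reported as a fixed-width window around the anchor.  Three
rule-based classifiers interpret the detected regions:

* acyltransferase (AT) substrate choice — the residues of a short specificity
  window downstream of the GHSxG active-site serine decide between
  malonyl-CoA (HAFH) and methylmalonyl-CoA (YASH);
* ketoreductase (KR) type — a B-type KR carries the conserved (L/V)D(D/N)
  motif and produces R-configured beta-hydroxyl groups; the A-type
  (tryptophan) criterion is a config-table rule marked "extrapolated" because
  only the B rule is motif-anchored in the primary literature this follows;
* catalytic activity — per-class essential-residue checks (KS cysteine, AT
  serine, DH histidine of HxxxGxxxxP, KR tyrosine, carrier-protein serine of
  the phosphopantetheine site).

Scanning is deterministic substring/regex matching over sliding windows, not
profile-HMM search: adequate for synthetic fixtures and for validating
pre-annotated coordinates, which always take precedence when supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

from .config import default_config

__all__ = [
    "DomainHit",
    "ATCall",
    "KRCall",
    "ActivityCall",
    "DOMAIN_CLASSES",
    "scan_domains",
    "classify_at_substrate",
    "classify_kr_type",
    "check_catalytic_activity",
]

DOMAIN_CLASSES = ("KS", "AT", "DH", "KR", "ER", "ACP", "TE")

MIN_SCAN_LENGTH = 50


@dataclass(frozen=True)
class DomainHit:
    """One detected catalytic domain (1-based inclusive aa coordinates)."""

    domain_class: str
    start_aa: int
    end_aa: int
    anchor_motif: str = ""
    source: str = "motif_scan"

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.start_aa > self.end_aa:
            raise ValueError("domain start_aa > end_aa")

    def region(self, protein_seq: str) -> str:
        return protein_seq[self.start_aa - 1 : self.end_aa]


@dataclass(frozen=True)
class ATCall:
    substrate: str  # malonyl | methylmalonyl | unknown
    signature_window: str = ""
    evidence: str = ""


@dataclass(frozen=True)
class KRCall:
    kr_type: str  # A | B | inactive | unknown
    motif: str = ""
    beta_oh_config: str = "none"  # R | S | none

    def __post_init__(self) -> None:
        if self.kr_type == "B" and self.beta_oh_config != "R":
            raise ValueError("B-type KR must predict R-configured beta-hydroxyl")
        if self.kr_type == "inactive" and self.beta_oh_config != "none":
            raise ValueError("inactive KR cannot assign a hydroxyl configuration")


@dataclass(frozen=True)
class ActivityCall:
    domain_class: str
    active: bool
    missing_residues: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.active != (len(self.missing_residues) == 0):
            raise ValueError("active must be true iff no residues are missing")


def _domain_cfg(config: Mapping[str, Any] | None) -> Mapping[str, Any]:
    return (config or default_config())["domains"]


def scan_domains(
    protein_seq: str,
    annotations: Iterable[DomainHit | tuple[str, int, int]] | None = None,
    config: Mapping[str, Any] | None = None,
) -> list[DomainHit]:
    """Locate PKS domains in a protein.

    If ``annotations`` (pre-annotated coordinates) are supplied they are
    validated against the sequence and passed through with
    ``source="annotation"``; otherwise a motif-anchored scan is run with the
    configured anchor table.  Hits are ordered by ``start_aa``; overlapping
    later hits are discarded in favour of the earlier anchor.
    """
    protein_seq = protein_seq.upper()
    if len(protein_seq) < MIN_SCAN_LENGTH:
        raise ValueError(f"sequence shorter than {MIN_SCAN_LENGTH} aa")

    domains = _domain_cfg(config)

    if annotations is not None:
        hits = []
        for ann in annotations:
            if isinstance(ann, DomainHit):
                cls, start, end = ann.domain_class, ann.start_aa, ann.end_aa
            else:
                cls, start, end = ann
            if start < 1 or end > len(protein_seq):
                raise ValueError(
                    f"annotation {cls} [{start},{end}] outside sequence "
                    f"of length {len(protein_seq)}"
                )
            region = protein_seq[start - 1 : end]
            match = re.search(domains[cls]["anchor"], region)
            hits.append(
                DomainHit(cls, start, end, match.group(0) if match else "", "annotation")
            )
        return sorted(hits, key=lambda h: h.start_aa)

    raw: list[DomainHit] = []
    for cls in DOMAIN_CLASSES:
        rules = domains[cls]
        lead, width = int(rules["lead"]), int(rules["width"])
        for match in re.finditer(rules["anchor"], protein_seq):
            start0 = max(0, match.start() - lead)
            end0 = min(len(protein_seq), start0 + width)
            raw.append(DomainHit(cls, start0 + 1, end0, match.group(0), "motif_scan"))

    raw.sort(key=lambda h: (h.start_aa, h.end_aa, h.domain_class))
    kept: list[DomainHit] = []
    for hit in raw:
        if kept and hit.start_aa <= kept[-1].end_aa:
            continue  # earlier anchor wins
        kept.append(hit)
    return kept


def classify_at_substrate(
    at_region: str, config: Mapping[str, Any] | None = None
) -> ATCall:
    """Call AT extender-unit choice from the specificity window.

    The window sits a configurable offset downstream of the GHSxG active-site
    serine; YASH calls methylmalonyl-CoA, HAFH malonyl-CoA, anything else is
    ``unknown``.
    """
    cfg = (config or default_config())["at"]
    at_region = at_region.upper()
    match = re.search(cfg["active_site"], at_region)
    if match is None:
        return ATCall("unknown", "", "no_active_site_motif")
    w_start = match.start() + int(cfg["window_offset"])
    w_end = w_start + int(cfg["window_len"])
    if w_end > len(at_region):
        return ATCall("unknown", "", "window_out_of_range")
    window = at_region[w_start:w_end]
    for substrate, pattern in cfg["patterns"].items():
        if re.fullmatch(pattern, window):
            return ATCall(substrate, window, f"window_match:{pattern}")
    return ATCall("unknown", window, "window_unmatched")


def classify_kr_type(
    kr_region: str, config: Mapping[str, Any] | None = None
) -> KRCall:
    """Call KR type and the implied beta-hydroxyl configuration.

    Precedence: a failed catalytic-tyrosine rule yields ``inactive``
    (no configuration); else a B motif in the typing window yields (B, R),
    an A-type tryptophan yields (A, S), and otherwise the call is unknown.
    """
    cfg = (config or default_config())["kr"]
    kr_region = kr_region.upper()
    if len(kr_region) < int(cfg["min_len"]):
        return KRCall("unknown", "", "none")
    if re.search(cfg["catalytic"], kr_region) is None:
        return KRCall("inactive", "", "none")

    anchor = (config or default_config())["domains"]["KR"]["anchor"]
    match = re.search(anchor, kr_region)
    lo, hi = (int(x) for x in cfg["type_window"])
    if match is not None:
        window = kr_region[match.end() + lo : match.end() + hi]
    else:  # no Rossmann anchor: search the whole region
        window = kr_region
    b_match = re.search(cfg["b_motif"], window)
    if b_match:
        return KRCall("B", b_match.group(0), "R")
    a_match = re.search(cfg["a_motif"], window)
    if a_match:
        return KRCall("A", a_match.group(0), "S")
    return KRCall("unknown", "", "none")


def check_catalytic_activity(
    hit: DomainHit,
    protein_seq: str,
    config: Mapping[str, Any] | None = None,
) -> ActivityCall:
    """Evaluate the per-class essential-residue rules on a detected domain."""
    domains = _domain_cfg(config)
    if hit.domain_class not in domains:
        raise ValueError(f"unknown domain class {hit.domain_class!r}")
    region = hit.region(protein_seq.upper())
    missing = tuple(
        rule
        for rule, pattern in domains[hit.domain_class].get("catalytic", {}).items()
        if re.search(pattern, region) is None
    )
    return ActivityCall(hit.domain_class, active=not missing, missing_residues=missing)
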