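"""Protein-level variant parsing, classification and channel-topology mapping.

SCN2A encodes the α-subunit of the neuronal voltage-gated sodium channel
Na_V_1.2: four homologous transmembrane domains (DI–DIV), each with six
helical segments (S1–S6) and a re-entrant pore loop between S5 and S6, joined
by cytoplasmic linkers and flanked by cytoplasmic N- and C-termini.

This module parses HGVS-style protein labels ("p.R853Q", "p.Arg853Gln",
"p.R102*", "p.T1420fs"), collapses the fine variant classes into the broad
missense / PTV (protein-truncating) / other partition used in the analyses,
maps missense positions onto a topology table of 1-based inclusive feature
intervals, and attaches functional gain-of-function (GoF) / loss-of-function
(LoF) labels: PTVs are LoF unconditionally, missense variants are looked up in
an electrophysiology evidence table, and mixed-effect variants stay
unclassified.
"""
from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils import seq1

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinChange",
    "VariantParseError",
    "parse_protein_variant",
    "format_protein_variant",
    "VAR_CLASSES",
    "PTV_CLASSES",
    "OTHER_CLASSES",
    "broad_class",
    "TopologyFeature",
    "Location",
    "ProteinTopology",
    "load_bundled_topology",
    "VariantRecord",
    "build_variant_records",
    "assign_function",
]

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

VAR_CLASSES = frozenset({
    "missense", "nonsense", "frameshift", "splice site",
    "in-frame deletion", "complex indel", "duplication", "deletion",
})
PTV_CLASSES = frozenset({"nonsense", "frameshift", "splice site", "deletion"})
OTHER_CLASSES = frozenset({"in-frame deletion", "complex indel", "duplication"})


class VariantParseError(ValueError):
    """An HGVS protein label could not be parsed; carries the raw label."""

    def __init__(self, label: str, reason: str = ""):
        self.label = label
        super().__init__(f"cannot parse protein variant {label!r}" + (f": {reason}" if reason else ""))


@dataclass(frozen=True)
class ProteinChange:
    """A normalized single-residue protein change.

    ``alt`` is a one-letter amino acid, ``"*"`` for a stop gain, or ``"fs"``
    for a frameshift.
    """

    ref_aa: str
    position: int
    alt: str

    def __post_init__(self):
        if self.ref_aa not in AA_LETTERS:
            raise VariantParseError(str(self), "invalid reference amino acid")
        if self.position < 1:
            raise VariantParseError(str(self), "position must be >= 1")
        if self.alt not in AA_LETTERS | {"*", "fs"}:
            raise VariantParseError(str(self), "invalid alternate residue")

    def __str__(self) -> str:
        return format_protein_variant(self)


_VARIANT_RE = re.compile(
    r"^p\.\(?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z*])"
    r"(?P<pos>[1-9]\d*)"
    r"(?P<alt>(?:[A-Z][a-z]{2}|[A-Z*])?fs(?:\*?\d+|Ter\d+)?|[A-Z][a-z]{2}|[A-Z*]|del|dup)?"
    r"\)?$"
)


def _to_one_letter(code: str, label: str) -> str:
    if len(code) == 1:
        aa = code
    else:
        if code == "Ter":
            return "*"
        aa = seq1(code)
    if aa == "*":
        return "*"
    if aa not in AA_LETTERS:
        raise VariantParseError(label, f"unknown amino-acid code {code!r}")
    return aa


def parse_protein_variant(label: str) -> ProteinChange:
    """Parse an HGVS-style protein label into a :class:`ProteinChange`.

    Accepts one- and three-letter codes, ``*``/``Ter`` stops and ``fs``
    frameshift markers, normalizing to one-letter form, e.g.
    ``"p.Arg853Gln" -> ProteinChange("R", 853, "Q")``.
    """
    raw = label.strip()
    if not raw.startswith("p."):
        raise VariantParseError(label, "label must begin with 'p.'")
    m = _VARIANT_RE.match(raw)
    if m is None:
        raise VariantParseError(label)
    ref = _to_one_letter(m.group("ref"), label)
    if ref == "*":
        raise VariantParseError(label, "reference residue cannot be a stop")
    alt_raw = m.group("alt")
    if alt_raw is None or alt_raw in ("del", "dup"):
        # "p.R853del" etc. carry no substitute residue; not a point substitution
        raise VariantParseError(label, "not a substitution, stop or frameshift")
    if "fs" in alt_raw:
        alt = "fs"
    else:
        alt = _to_one_letter(alt_raw, label)
    return ProteinChange(ref, int(m.group("pos")), alt)


def format_protein_variant(change: ProteinChange) -> str:
    """One-letter HGVS-style rendering, the inverse of :func:`parse_protein_variant`."""
    return f"p.{change.ref_aa}{change.position}{change.alt}"


def broad_class(var_class: str) -> str:
    """Collapse a fine variant class into missense / PTV / other.

    Nonsense, frameshift, splice-site and (whole-gene) deletion variants all
    truncate or remove the protein and are pooled as PTV; in-frame deletions,
    complex indels and duplications are 'other' and are excluded from
    variant-class analyses.
    """
    if var_class not in VAR_CLASSES:
        raise ValueError(f"unknown variant class {var_class!r}; expected one of {sorted(VAR_CLASSES)}")
    if var_class == "missense":
        return "missense"
    if var_class in PTV_CLASSES:
        return "PTV"
    return "other"


@dataclass(frozen=True)
class TopologyFeature:
    """One annotated interval of the channel, 1-based inclusive coordinates."""

    domain: str | None  # "I".."IV" for domain-associated features, else None
    region: str         # Cytoplasmic / Extracellular / Transmembrane / Pore-forming
    segment: str | None  # "S1".."S6" for transmembrane helices, else None
    start: int
    end: int


@dataclass(frozen=True)
class Location:
    """Resolved location labels for one protein position."""

    domain: str | None
    region: str
    segment: str | None
    pore_loop: bool

    @property
    def table_label(self) -> str:
        """Coarse label in the style of clinical variant tables."""
        if self.region == "Transmembrane" and self.domain:
            return f"Helical repeat {self.domain}"
        return self.region


class ProteinTopology:
    """Ordered, non-overlapping feature intervals covering a channel protein.

    The S5–S6 *pore loop* of each domain is a derived flag: any position
    strictly between the end of that domain's S5 helix and the start of its S6
    helix is pore-loop territory (this includes the narrow pore-forming
    re-entrant segment and its short extracellular flanks).
    """

    def __init__(self, features: Iterable[TopologyFeature]):
        self.features = sorted(features, key=lambda f: f.start)
        for f in self.features:
            if f.start < 1 or f.end < f.start:
                raise ValueError(f"bad interval {f}")
        for prev, nxt in zip(self.features, self.features[1:]):
            if nxt.start <= prev.end:
                raise ValueError(f"overlapping features {prev} / {nxt}")
        self.length = self.features[-1].end if self.features else 0
        self._pore_spans: dict[str, tuple[int, int]] = {}
        segs = {
            (f.domain, f.segment): f
            for f in self.features
            if f.segment in ("S5", "S6") and f.domain
        }
        for domain in sorted({d for d, _ in segs}):
            s5, s6 = segs.get((domain, "S5")), segs.get((domain, "S6"))
            if s5 and s6 and s5.end < s6.start:
                self._pore_spans[domain] = (s5.end + 1, s6.start - 1)

    @property
    def pore_loop_spans(self) -> Mapping[str, tuple[int, int]]:
        """Per-domain (start, end) of the derived S5–S6 pore-loop region."""
        return dict(self._pore_spans)

    def locate(self, position: int) -> Location:
        """Resolve a 1-based protein position to its location labels.

        Positions inside the protein but outside every annotated feature get
        region ``"unannotated"`` rather than an error; positions outside
        ``[1, length]`` raise ``ValueError``.
        """
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside protein [1, {self.length}]")
        pore = any(lo <= position <= hi for lo, hi in self._pore_spans.values())
        for f in self.features:
            if f.start <= position <= f.end:
                return Location(f.domain, f.region, f.segment, pore)
        return Location(None, "unannotated", None, pore)

    @classmethod
    def from_tsv(cls, path) -> "ProteinTopology":
        """Read a feature table: columns domain, region, segment, start, end.

        ``#`` lines are comments; '-' or empty marks a missing domain/segment.
        """
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"domain", "region", "segment", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"topology table missing column(s): {sorted(missing)}")

        def clean(v):
            v = (v or "").strip()
            return None if v in ("", "-") else v

        feats = [
            TopologyFeature(
                clean(row["domain"]), str(row["region"]).strip(),
                clean(row["segment"]), int(row["start"]), int(row["end"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(feats)


def load_bundled_topology() -> ProteinTopology:
    """The package's approximate Na_V_1.2 topology fixture (see its header)."""
    ref = importlib.resources.files("scn2a_pheno.data") / "nav12_topology_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return ProteinTopology.from_tsv(path)


@dataclass
class VariantRecord:
    """One individual's variant with derived classifications."""

    individual_id: str
    label: str
    var_class: str
    phenotype_group: str = ""
    change: ProteinChange | None = None
    broad: str = field(default="")
    location: Location | None = None
    functional: str = "unclassified"  # GoF / LoF / unclassified


def build_variant_records(
    table: pd.DataFrame,
    topology: ProteinTopology | None = None,
    evidence: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Build :class:`VariantRecord` objects from a variant table.

    *table* needs columns ``individual_id``, ``variant`` (HGVS p. label or raw
    DNA-level label for non-missense events) and ``var_class``; an optional
    ``phenotype_group`` column is carried through, and an optional
    ``functional_evidence`` column is folded into the evidence mapping.
    Missense labels are parsed and, when *topology* is given, located on the
    channel; frameshift/splice records have no meaningful protein position and
    keep ``location=None``.
    """
    required = {"individual_id", "variant", "var_class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing column(s): {sorted(missing)}")
    ev: dict[str, str] = dict(evidence or {})
    if "functional_evidence" in table.columns:
        for _, row in table.iterrows():
            val = str(row["functional_evidence"] or "").strip()
            if not val or val.lower() == "nan":
                continue
            label = str(row["variant"])
            key = _normalize_label(label)
            if key in ev and ev[key] != val:
                raise ValueError(f"contradictory functional evidence for {label!r}")
            ev[key] = val

    records = []
    for _, row in table.iterrows():
        var_class = str(row["var_class"]).strip()
        rec = VariantRecord(
            individual_id=str(row["individual_id"]),
            label=str(row["variant"]).strip(),
            var_class=var_class,
            phenotype_group=str(row.get("phenotype_group", "") or ""),
            broad=broad_class(var_class),
        )
        if rec.label.startswith("p."):
            try:
                rec.change = parse_protein_variant(rec.label)
                rec.label = format_protein_variant(rec.change)
            except VariantParseError:
                if rec.broad == "missense":
                    raise
        if (
            rec.broad == "missense"
            and topology is not None
            and rec.change is not None
            and 1 <= rec.change.position <= topology.length
        ):
            rec.location = topology.locate(rec.change.position)
        records.append(rec)
    return assign_function(records, ev)


def _normalize_label(label: str) -> str:
    label = label.strip()
    if label.startswith("p."):
        try:
            return format_protein_variant(parse_protein_variant(label))
        except VariantParseError:
            return label
    return label


def assign_function(
    records: list[VariantRecord],
    evidence: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Attach GoF/LoF labels in place and return the records.

    PTVs become LoF unconditionally.  Missense variants are looked up in the
    evidence mapping (variant label -> ``"GoF"``/``"LoF"``/``"mixed"``);
    mixed-effect variants and variants absent from the evidence stay
    ``unclassified`` and are excluded from function-based analyses.
    """
    ev = {_normalize_label(k): v for k, v in (evidence or {}).items()}
    for k, v in ev.items():
        if v not in ("GoF", "LoF", "mixed"):
            raise ValueError(f"evidence for {k!r} must be GoF, LoF or mixed, got {v!r}")
    for rec in records:
        if rec.broad == "PTV":
            rec.functional = "LoF"
        elif rec.broad == "missense":
            label = _normalize_label(rec.label)
            val = ev.get(label, "unclassified")
            rec.functional = val if val in ("GoF", "LoF") else "unclassified"
        else:
            rec.functional = "unclassified"
    return records
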