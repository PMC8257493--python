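"""Tab-separated dialects for annotations, variants and functional evidence.

Annotation tables carry one row per assertion: ``individual_id``, ``term``
(an ``HP:`` CURIE, or the ``NP:`` shorthand marking an *absent* phenotype) and
an optional ``polarity`` column ('positive'/'negative') which, when present,
overrides the prefix.  Negative assertions are stored internally as ``HP:``
ids with a polarity flag; the ``NP:`` spelling exists only at I/O.
"""
from __future__ import annotations

import re

import pandas as pd

NEGATIVE_PREFIX = "NP:"
_CURIE_RE = re.compile(r"^[A-Z]+:\d{7}$")

__all__ = ["read_annotations", "write_annotations", "read_variants",
           "read_evidence", "NEGATIVE_PREFIX"]


def _split_polarity(term: str) -> tuple[str, str]:
    term = term.strip()
    if not _CURIE_RE.match(term):
        raise ValueError(f"malformed term CURIE {term!r} (expected prefix:7 digits)")
    if term.startswith(NEGATIVE_PREFIX):
        return "HP:" + term.split(":", 1)[1], "negative"
    return term, "positive"


def read_annotations(source) -> pd.DataFrame:
    """Read an annotation TSV into (individual_id, term, polarity) long format."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if not {"individual_id", "term"} <= set(df.columns):
        raise ValueError("annotation table needs individual_id and term columns")
    terms, polarities = zip(*(_split_polarity(t) for t in df["term"])) if len(df) else ((), ())
    out = pd.DataFrame({
        "individual_id": df["individual_id"].astype(str),
        "term": list(terms),
        "polarity": list(polarities),
    })
    if "polarity" in df.columns:
        explicit = df["polarity"].fillna("").str.strip().str.lower()
        override = explicit.isin(["positive", "negative"])
        out.loc[override.to_numpy(), "polarity"] = explicit[override].to_numpy()
    bad = ~out["polarity"].isin(["positive", "negative"])
    if bad.any():
        raise ValueError(f"invalid polarity values: {sorted(out.loc[bad, 'polarity'].unique())}")
    return out


def write_annotations(df: pd.DataFrame, path, np_shorthand: bool = True) -> None:
    """Write long-format annotations, rendering negatives with the NP: prefix."""
    out = df.copy()
    if np_shorthand:
        neg = out["polarity"] == "negative"
        out.loc[neg, "term"] = NEGATIVE_PREFIX + out.loc[neg, "term"].str.split(":").str[1]
    out.to_csv(path, sep="\t", index=False)


def read_variants(source) -> pd.DataFrame:
    """Read a variant TSV (individual_id, variant, var_class, ...)."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#").fillna("")
    missing = {"individual_id", "variant", "var_class"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing column(s): {sorted(missing)}")
    return df


def read_evidence(source) -> dict[str, str]:
    """Read a two-column (variant, effect) functional-evidence TSV."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if not {"variant", "effect"} <= set(df.columns):
        raise ValueError("evidence table needs variant and effect columns")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        v, e = str(row["variant"]).strip(), str(row["effect"]).strip()
        if v in out and out[v] != e:
            raise ValueError(f"contradictory evidence rows for {v!r}")
        out[v] = e
    return out
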