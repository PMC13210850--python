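"""Promoter cis-element scanning and five-class functional summary.

Promoters (typically the 2000 bp upstream of a gene) are scanned against a
configurable dictionary of named IUPAC patterns, each assigned to one of five
functional classes: hormone, stress, light, development, other. Every
occurrence on either strand is counted (overlaps included; a palindromic
pattern at a position counts once per strand), with positions reported 0-based
on the forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "FUNCTIONAL_CLASSES",
    "IUPAC_CODES",
    "MotifDictionary",
    "MotifEntry",
    "reverse_complement",
    "load_dictionary",
    "default_dictionary",
    "scan_promoter",
    "scan_promoter_set",
    "classify_and_summarize",
    "extract_promoters",
    "PromoterSummary",
]

FUNCTIONAL_CLASSES = ("hormone", "stress", "light", "development", "other")

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a nucleotide string, IUPAC codes included."""
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifEntry:
    name: str
    patterns: tuple[str, ...]
    functional_class: str

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"{self.name}: class {self.functional_class!r} not one of {FUNCTIONAL_CLASSES}"
            )
        for pat in self.patterns:
            bad = set(pat) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{self.name}: non-IUPAC characters {sorted(bad)} in {pat!r}")


@dataclass
class MotifDictionary:
    """Named IUPAC cis-element patterns, each mapped to one functional class."""

    entries: dict[str, MotifEntry]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping]) -> "MotifDictionary":
        entries = {}
        for name, spec in mapping.items():
            pats = spec["patterns"] if "patterns" in spec else [spec["pattern"]]
            entries[name] = MotifEntry(name, tuple(p.upper() for p in pats), spec["class"])
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def classes(self) -> dict[str, str]:
        return {n: e.functional_class for n, e in self.entries.items()}


def load_dictionary(path) -> MotifDictionary:
    with open(path) as fh:
        return MotifDictionary.from_mapping(yaml.safe_load(fh))


def default_dictionary() -> MotifDictionary:
    """Starter dictionary of canonical consensus strings for common plant
    cis-elements (ABRE family, MeJA/SA/auxin/GA hormone motifs, drought/
    low-temperature/defense stress motifs, light-responsive boxes, development
    motifs and core-promoter elements)."""
    ref = resources.files("coldkit.data").joinpath("cis_elements.yaml")
    with ref.open() as fh:
        return MotifDictionary.from_mapping(yaml.safe_load(fh))


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all captured
    body = "".join(
        b if len(IUPAC_CODES[b]) == 1 else "[" + "".join(sorted(IUPAC_CODES[b])) + "]"
        for b in pattern
    )
    return re.compile(f"(?=({body}))")


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return sequence


def scan_promoter(sequence: str, dictionary: MotifDictionary) -> pd.DataFrame:
    """Scan one promoter; returns a hit table.

    Columns: element, functional_class, pattern, position (0-based,
    forward strand), strand, match (forward-strand substring). Minus-strand
    hits are matches of the reverse-complemented pattern on the forward
    sequence. ``N`` in the sequence never matches (regex classes contain only
    concrete bases).
    """
    sequence = _validate_sequence(sequence)
    hits = []
    for entry in dictionary.entries.values():
        for pattern in entry.patterns:
            for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
                for m in _pattern_regex(pat).finditer(sequence):
                    hits.append(
                        (entry.name, entry.functional_class, pattern,
                         m.start(), strand, m.group(1))
                    )
    df = pd.DataFrame(
        hits, columns=["element", "functional_class", "pattern", "position", "strand", "match"]
    )
    return df.sort_values(["position", "element", "strand"], kind="stable").reset_index(drop=True)


def scan_promoter_set(
    promoters: Mapping[str, str], dictionary: MotifDictionary
) -> pd.DataFrame:
    """Scan a set of promoters; hit table gains a leading ``promoter`` column."""
    frames = []
    for pid, seq in promoters.items():
        df = scan_promoter(seq, dictionary)
        df.insert(0, "promoter", pid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["promoter", "element", "functional_class", "pattern",
                     "position", "strand", "match"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PromoterSummary:
    per_element: pd.Series            # total occurrences per element
    per_class: pd.Series              # total occurrences per functional class
    joint_fraction: float             # promoters with hormone+stress+light (or union)
    joint_mode: str                   # "all" or "any"
    n_promoters: int
    ranking: pd.Series                # elements by abundance, class "other" excluded


def classify_and_summarize(
    hits: pd.DataFrame,
    promoter_ids: Iterable[str],
    dictionary: MotifDictionary,
    joint_mode: str = "all",
) -> PromoterSummary:
    """Per-element/per-class totals and the hormone/stress/light joint statistic.

    ``joint_mode="all"`` counts promoters containing at least one element of
    each of the hormone, stress and light classes simultaneously;
    ``"any"`` counts promoters containing at least one element of the union.
    """
    if joint_mode not in ("all", "any"):
        raise ValueError("joint_mode must be 'all' or 'any'")
    promoter_ids = list(promoter_ids)
    element_names = list(dictionary.entries)
    per_element = (
        hits["element"].value_counts().reindex(element_names, fill_value=0).astype(int)
    )
    classes = dictionary.classes()
    per_class = pd.Series(0, index=list(FUNCTIONAL_CLASSES), dtype=int)
    for name, count in per_element.items():
        per_class[classes[name]] += count
    trio = ("hormone", "stress", "light")
    if hits.empty:
        n_joint = 0
    else:
        present = (
            hits.groupby("promoter")["functional_class"]
            .agg(lambda s: frozenset(s))
        )
        if joint_mode == "all":
            n_joint = sum(1 for pid in promoter_ids
                          if pid in present.index and all(c in present[pid] for c in trio))
        else:
            n_joint = sum(1 for pid in promoter_ids
                          if pid in present.index and any(c in present[pid] for c in trio))
    ranking = (
        per_element[[n for n in element_names if classes[n] != "other"]]
        .sort_values(ascending=False, kind="stable")
    )
    return PromoterSummary(
        per_element=per_element,
        per_class=per_class,
        joint_fraction=n_joint / len(promoter_ids) if promoter_ids else 0.0,
        joint_mode=joint_mode,
        n_promoters=len(promoter_ids),
        ranking=ranking,
    )


def extract_promoters(
    genome: Mapping[str, str], gene_map: pd.DataFrame, length: int = 2000
) -> dict[str, str]:
    """Slice upstream promoter regions from contig sequences.

    Uses half-open coordinates from the gene map (gene_id, chromosome, start,
    end, strand); for minus-strand genes the region downstream of ``end`` is
    taken and reverse-complemented. Regions are clipped at contig edges.
    """
    out = {}
    for row in gene_map.itertuples():
        contig = genome[row.chromosome]
        if row.strand == "+":
            lo = max(0, row.start - length)
            out[row.gene_id] = contig[lo:row.start].upper()
        else:
            hi = min(len(contig), row.end + length)
            out[row.gene_id] = reverse_complement(contig[row.end:hi].upper())
    return out
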