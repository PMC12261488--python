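"""Assembly, filtering, labelling, and splitting of TCR–epitope datasets.

Covers the length filter (CDR3β of 7–24 residues), the two negative-sampling
constructions (random epitope pairing against a healthy-donor pool, and
pairing against a curated negative-epitope list), the 50/50 split between the
generation and prediction tasks, and TSV/CSV round-trip IO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .seq_codec import back_translate

__all__ = [
    "MIN_CDR3B_LEN",
    "MAX_CDR3B_LEN",
    "TcrRecord",
    "BindingPair",
    "filter_by_length",
    "dedupe_pairs",
    "make_negatives",
    "split_halves",
    "read_pairs",
    "write_pairs",
]

logger = logging.getLogger(__name__)

MIN_CDR3B_LEN = 7
MAX_CDR3B_LEN = 24


class SchemaError(ValueError):
    pass


class SamplingExhaustedError(RuntimeError):
    pass


@dataclass
class TcrRecord:
    """One CDR3β observation."""

    cdr3b: str
    nt: str | None = None
    epitope: str | None = None
    hla_locus: str | None = None  # "A" | "B" | "C"
    label: int | None = None
    source: str = ""

    def with_nt(self) -> "TcrRecord":
        if self.nt is None:
            self.nt = back_translate(self.cdr3b)
        return self


@dataclass
class BindingPair:
    """A (TCR, epitope) pair with a binary binding label."""

    tcr: TcrRecord
    epitope: str
    label: int
    negative_mode: str = "none"  # none | random | iedb
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label == 0 and self.negative_mode == "none":
            raise ValueError("negative pairs must carry a negative_mode")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tcr.cdr3b, self.epitope)


def filter_by_length(records: list[TcrRecord]) -> list[TcrRecord]:
    """Retain records with 7 ≤ len(cdr3b) ≤ 24, preserving order."""
    kept = [r for r in records if MIN_CDR3B_LEN <= len(r.cdr3b) <= MAX_CDR3B_LEN]
    removed = len(records) - len(kept)
    if removed:
        logger.info("length filter removed %d of %d records", removed, len(records))
    return kept


def dedupe_pairs(pairs: list[BindingPair]) -> list[BindingPair]:
    """Drop duplicate (cdr3b, epitope) pairs, keeping first occurrence."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    if len(out) < len(pairs):
        logger.info("deduplicated %d duplicate pairs", len(pairs) - len(out))
    return out


def make_negatives(
    healthy_pool: list[TcrRecord],
    epitopes: list[str],
    n: int,
    mode: str = "random",
    positives: set[tuple[str, str]] | None = None,
    seed: int = 0,
    max_attempts_factor: int = 100,
) -> list[BindingPair]:
    """Pair healthy-donor TCRs with epitopes to form labelled non-binders.

    ``mode="random"`` draws epitopes from the positive set's epitopes;
    ``mode="iedb"`` expects a caller-supplied negative-epitope list. Emitted
    pairs never collide with ``positives`` and never repeat; sampling is
    uniform and deterministic for a given seed.
    """
    import numpy as np

    if mode not in ("random", "iedb"):
        raise ValueError(f"unknown mode {mode!r}")
    if not healthy_pool or not epitopes:
        raise ValueError("healthy pool and epitope list must be non-empty")
    if n < 0:
        raise ValueError("n must be >= 0")
    positives = positives or set()
    rng = np.random.default_rng(seed)
    out: list[BindingPair] = []
    emitted: set[tuple[str, str]] = set()
    attempts = 0
    budget = max(n, 1) * max_attempts_factor
    while len(out) < n:
        if attempts >= budget:
            raise SamplingExhaustedError(
                f"could not find {n} distinct negative pairs after {attempts} draws"
            )
        attempts += 1
        tcr = healthy_pool[int(rng.integers(len(healthy_pool)))]
        epi = epitopes[int(rng.integers(len(epitopes)))]
        key = (tcr.cdr3b, epi)
        if key in positives or key in emitted:
            continue
        emitted.add(key)
        out.append(
            BindingPair(
                tcr=TcrRecord(
                    cdr3b=tcr.cdr3b, nt=tcr.nt, hla_locus=tcr.hla_locus,
                    label=0, source=tcr.source,
                ),
                epitope=epi,
                label=0,
                negative_mode=mode,
            )
        )
    return out


def split_halves(pairs: list, seed: int = 0) -> tuple[list, list]:
    """Uniformly random disjoint 50/50 partition (sizes differ by ≤ 1)."""
    import numpy as np

    if len(pairs) < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    half = len(pairs) // 2
    first = [pairs[i] for i in sorted(order[:half])]
    second = [pairs[i] for i in sorted(order[half:])]
    return first, second


_MANDATORY = ["cdr3b", "epitope"]


def read_pairs(path: str, fmt: str = "tsv") -> list[BindingPair]:
    """Read binding pairs from a TSV/CSV with columns cdr3b, epitope[, hla, label]."""
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    known = {"cdr3b", "epitope", "hla", "label", "negative_mode", "nt", "source"}
    pairs = []
    for _, row in df.iterrows():
        label = int(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else 1
        mode = (
            str(row["negative_mode"])
            if "negative_mode" in df.columns and pd.notna(row["negative_mode"])
            else ("none" if label == 1 else "random")
        )
        hla = str(row["hla"]) if "hla" in df.columns and pd.notna(row["hla"]) else None
        nt = str(row["nt"]) if "nt" in df.columns and pd.notna(row["nt"]) else None
        source = str(row["source"]) if "source" in df.columns and pd.notna(row["source"]) else ""
        extra = {c: row[c] for c in df.columns if c not in known}
        pairs.append(
            BindingPair(
                tcr=TcrRecord(cdr3b=str(row["cdr3b"]), nt=nt, epitope=str(row["epitope"]),
                              hla_locus=hla, label=label, source=source),
                epitope=str(row["epitope"]),
                label=label,
                negative_mode=mode,
                extra=extra,
            )
        )
    return pairs


def write_pairs(pairs: list[BindingPair], path: str, fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    rows = []
    for p in pairs:
        row = {
            "cdr3b": p.tcr.cdr3b,
            "epitope": p.epitope,
            "hla": p.tcr.hla_locus if p.tcr.hla_locus is not None else "",
            "label": p.label,
            "negative_mode": p.negative_mode,
            "nt": p.tcr.nt if p.tcr.nt is not None else "",
            "source": p.tcr.source,
        }
        row.update(p.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
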