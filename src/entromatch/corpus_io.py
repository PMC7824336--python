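"""Corpus reading, pattern sampling, synthetic corpora and result tables.

Domain texts come in two flavours: DNA as FASTA (records concatenated,
uppercased, optionally restricted to the {A, C, G, T} alphabet) and
natural-language plain text (case, spaces and punctuation preserved --
they are real symbols for pattern entropy).  Campaign patterns are
substrings sampled at random offsets, cycling through the requested
length set so each length is equally represented; sampling is seeded and
de-duplicated.

The synthetic generators stand in for genome and book downloads so that
every pipeline stage is testable offline: i.i.d. text over an arbitrary
alphabet with a configurable symbol distribution, with presets for
uniform DNA and a skewed English-like letter distribution.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model_pipeline import CampaignRecord

__all__ = [
    "Corpus",
    "PatternSet",
    "read_fasta",
    "read_plain_text",
    "sample_patterns",
    "generate_synthetic_corpus",
    "synthetic_dna_corpus",
    "synthetic_english_corpus",
    "write_results",
    "read_results",
    "DNA_ALPHABET",
    "ENGLISH_ALPHABET",
    "ENGLISH_FREQUENCIES",
]

logger = logging.getLogger(__name__)

DNA_ALPHABET: Tuple[str, ...] = ("A", "C", "G", "T")

# Letter frequencies of running English text (Lewand's ordering), plus the
# space at roughly the word-boundary rate; normalized at build time.
_ENGLISH_WEIGHTS: Dict[str, float] = {
    " ": 18.0,
    "e": 10.2,
    "t": 7.5,
    "a": 6.5,
    "o": 6.2,
    "i": 5.7,
    "n": 5.6,
    "s": 5.3,
    "h": 5.0,
    "r": 5.0,
    "d": 3.5,
    "l": 3.3,
    "u": 2.3,
    "c": 2.2,
    "m": 2.0,
    "w": 2.0,
    "f": 1.9,
    "g": 1.6,
    "y": 1.6,
    "p": 1.5,
    "b": 1.2,
    "v": 0.8,
    "k": 0.6,
    "j": 0.12,
    "x": 0.12,
    "q": 0.08,
    "z": 0.06,
}
ENGLISH_ALPHABET: Tuple[str, ...] = tuple(_ENGLISH_WEIGHTS)
_total = sum(_ENGLISH_WEIGHTS.values())
ENGLISH_FREQUENCIES: Tuple[float, ...] = tuple(
    w / _total for w in _ENGLISH_WEIGHTS.values()
)


@dataclass(frozen=True)
class Corpus:
    """A domain text: identifier, alphabet actually present, characters."""

    identifier: str
    alphabet: frozenset
    text: str
    source_format: str


@dataclass(frozen=True)
class PatternSet:
    """Sampled campaign patterns with their sampling provenance."""

    patterns: Tuple[str, ...]
    lengths: Tuple[int, ...]
    seed: Optional[int]
    corpus_id: str


def read_fasta(path: str | Path, strict: bool = True) -> Corpus:
    """Concatenate all FASTA records into one uppercased DNA text.

    In strict mode characters outside {A, C, G, T} (ambiguity codes such
    as N) are removed and the removal count logged; genomes routinely
    contain them but the campaign alphabet is strictly the four bases.
    """
    path = Path(path)
    parts: List[str] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        parts.append(str(record.seq).upper())
    if n_records == 0:
        raise ValueError(f"{path}: no FASTA records found")
    text = "".join(parts)
    if not text:
        raise ValueError(f"{path}: FASTA records contain no sequence")
    if strict:
        kept = "".join(c for c in text if c in "ACGT")
        removed = len(text) - len(kept)
        if removed:
            logger.info("%s: removed %d non-ACGT characters", path, removed)
        text = kept
        if not text:
            raise ValueError(f"{path}: no A/C/G/T characters after filtering")
    return Corpus(
        identifier=path.name,
        alphabet=frozenset(text),
        text=text,
        source_format="fasta",
    )


def read_plain_text(path: str | Path, newline: str = "space") -> Corpus:
    """Read a natural-language text, preserving case and punctuation.

    CRLF line endings are normalized to LF first.  ``newline`` controls
    what a line break becomes: ``"space"`` (default, so patterns can span
    line breaks), ``"keep"`` or ``"strip"``.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8", errors="replace")
    raw = raw.replace("\r\n", "\n").replace("\r", "\n")
    if newline == "space":
        text = raw.replace("\n", " ")
    elif newline == "strip":
        text = raw.replace("\n", "")
    elif newline == "keep":
        text = raw
    else:
        raise ValueError(f"unknown newline policy {newline!r}")
    if not text:
        raise ValueError(f"{path}: file is empty")
    return Corpus(
        identifier=path.name,
        alphabet=frozenset(text),
        text=text,
        source_format="txt",
    )


def sample_patterns(
    corpus: Corpus,
    lengths: Sequence[int],
    count: int,
    seed: int,
    max_attempts_per_pattern: int = 200,
) -> PatternSet:
    """Draw ``count`` distinct substrings of the corpus as campaign patterns.

    Offsets are uniform; lengths cycle through the (sorted) length set so
    the length histogram stays balanced up to rounding.  A length whose
    distinct substrings are exhausted (e.g. the 16 possible DNA 2-mers)
    is skipped after a bounded number of re-draws and the remaining
    lengths absorb its slots.  Raises if the corpus cannot supply enough
    distinct substrings overall, naming the count achieved.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    lengths = tuple(sorted(set(int(L) for L in lengths)))
    if not lengths:
        raise ValueError("lengths must be nonempty")
    if any(L < 1 for L in lengths):
        raise ValueError("every length must be >= 1")
    n = len(corpus.text)
    if any(L > n for L in lengths):
        raise ValueError("every length must be <= the corpus text length")
    rng = random.Random(seed)
    seen = set()
    patterns: List[str] = []
    budget = max_attempts_per_pattern * count
    attempts = 0
    li = 0
    stale_rounds = 0
    while len(patterns) < count and attempts < budget and stale_rounds < len(lengths):
        L = lengths[li % len(lengths)]
        accepted = False
        for _ in range(max_attempts_per_pattern):
            off = rng.randrange(0, n - L + 1)
            p = corpus.text[off : off + L]
            attempts += 1
            if p not in seen:
                seen.add(p)
                patterns.append(p)
                accepted = True
                break
            if attempts >= budget:
                break
        stale_rounds = 0 if accepted else stale_rounds + 1
        li += 1
    if len(patterns) < count:
        raise RuntimeError(
            f"could only sample {len(patterns)} of {count} distinct patterns "
            f"from corpus {corpus.identifier!r} within {budget} attempts"
        )
    return PatternSet(
        patterns=tuple(patterns),
        lengths=lengths,
        seed=seed,
        corpus_id=corpus.identifier,
    )


def generate_synthetic_corpus(
    alphabet: Sequence[str],
    frequencies: Sequence[float],
    length: int,
    seed: int,
    identifier: str = "synthetic",
) -> Corpus:
    """I.i.d. synthetic text over ``alphabet`` with the given symbol law."""
    if len(alphabet) != len(frequencies):
        raise ValueError("alphabet and frequencies must have equal length")
    if length < 1:
        raise ValueError("length must be >= 1")
    freqs = np.asarray(frequencies, dtype=float)
    if abs(float(freqs.sum()) - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(alphabet), size=length, p=freqs)
    symbols = list(alphabet)
    text = "".join(symbols[i] for i in draws)
    return Corpus(
        identifier=identifier,
        alphabet=frozenset(text),
        text=text,
        source_format="synthetic",
    )


def synthetic_dna_corpus(
    length: int,
    seed: int,
    frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> Corpus:
    """Uniform (by default) i.i.d. DNA text over {A, C, G, T}."""
    return generate_synthetic_corpus(
        DNA_ALPHABET, frequencies, length, seed, identifier="synthetic-dna"
    )


def synthetic_english_corpus(length: int, seed: int) -> Corpus:
    """English-like i.i.d. text with a skewed letter/space distribution."""
    return generate_synthetic_corpus(
        ENGLISH_ALPHABET,
        ENGLISH_FREQUENCIES,
        length,
        seed,
        identifier="synthetic-english",
    )


# ---------------------------------------------------------------------------
# campaign result tables

_COLUMNS = ["pattern", "m", "Algo", "comp", "PattEnt", "PattEntRound", "PattEntClass"]


def write_results(records: Sequence[CampaignRecord], path: str | Path) -> None:
    """Write campaign records as CSV (columns pattern..PattEntClass)."""
    if not records:
        raise ValueError("records must be nonempty")
    df = pd.DataFrame(
        {
            "pattern": [r.pattern for r in records],
            "m": [r.m for r in records],
            "Algo": [r.algo for r in records],
            "comp": [r.comp for r in records],
            "PattEnt": [repr(r.patt_ent) for r in records],
            "PattEntRound": [f"{r.patt_ent_round:.2f}" for r in records],
            "PattEntClass": [r.patt_ent_class for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> List[CampaignRecord]:
    """Read a campaign CSV back into records (round-trips write_results)."""
    df = pd.read_csv(path, dtype={"pattern": str}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CampaignRecord(
            pattern=str(row.pattern),
            algo=str(row.Algo),
            m=int(row.m),
            comp=int(row.comp),
            patt_ent=float(row.PattEnt),
            patt_ent_round=float(row.PattEntRound),
            patt_ent_class=int(row.PattEntClass),
        )
        for row in df.itertuples(index=False)
    ]
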