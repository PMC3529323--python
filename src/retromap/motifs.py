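"""IUPAC promoter-motif scanning and over-representation.

Counts occurrences of degenerate transcription-factor binding motifs
(W-box, G-box/ABRE, GCC-box, Evening Element, I-box, ...) in promoter
sequences, on the forward strand or both strands, and tests foreground
promoter sets (e.g. marker-gene promoters) for motif over-representation
against a background set.

Counting convention: an occurrence is a distinct start position on the
forward coordinate system where the motif — or, when scanning both
strands, its reverse complement — matches under IUPAC degeneracy.
Overlapping occurrences all count; a position where both strands match
(a palindromic site) counts once. ``N`` in a sequence matches no motif
letter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.base import BaseEstimator, TransformerMixin

from retromap import enrichment as _enrichment
from scipy import stats

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement_iupac(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A named degenerate nucleotide consensus."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in {self.name!r}: {sorted(bad)}")
        if len(self.iupac) < 4:
            raise ValueError(f"motif {self.name!r} shorter than 4 bases")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


#: Default library of the motifs recurring in organelle-perturbation marker
#: promoters. Consensus strings are conventional definitions from the plant
#: cis-element literature; the library is a declared, editable input, not
#: ground truth.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("W-box", "TTGACY"),
    Motif("T-box", "ACTTTG"),
    Motif("G-box", "CACGTG"),
    Motif("ABRE", "ACGTGKC"),
    Motif("Evening-Element", "AAAATATCT"),
    Motif("I-box", "GATAAG"),
    Motif("GCC-box", "GCCGCC"),
)


def _regex(motif_str: str) -> re.Pattern:
    # sequence N must match nothing: character classes list concrete bases
    # only, so an N in the sequence never satisfies them
    return re.compile(
        "(?=" + "".join(f"[{IUPAC[c]}]" for c in motif_str) + ")"
    )


def _match_positions(seq: str, motif_str: str) -> set[int]:
    return {m.start() for m in _regex(motif_str).finditer(seq)}


def scan_promoter(seq: str, motif: Motif, strands: str = "both") -> int:
    """Number of motif occurrence positions in one sequence.

    ``strands='both'`` also matches the reverse complement of the motif at
    each forward-strand position; a palindromic site counts once.
    """
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide letters: {sorted(bad)}")
    positions = _match_positions(seq, motif.iupac)
    if strands == "both":
        positions |= _match_positions(seq, reverse_complement_iupac(motif.iupac))
    return len(positions)


@dataclass
class MotifCountTable:
    """Per-promoter occurrence counts plus scannable position counts.

    ``counts`` is promoters x motifs; ``n_positions`` gives, per promoter
    and motif, the number of candidate start positions
    (len(seq) - len(motif) + 1), needed for rate-based enrichment.
    """

    counts: pd.DataFrame
    n_positions: pd.DataFrame

    def presence(self, motif_name: str) -> set[str]:
        """Promoter ids containing at least one occurrence of the motif."""
        col = self.counts[motif_name]
        return set(col.index[col > 0])


def scan_promoters(
    sequences: dict[str, str],
    motifs: tuple[Motif, ...] | list[Motif] = DEFAULT_MOTIFS,
    strands: str = "both",
) -> MotifCountTable:
    """Scan a promoter set against a motif library."""
    names = [m.name for m in motifs]
    counts = pd.DataFrame(0, index=list(sequences), columns=names, dtype=int)
    npos = pd.DataFrame(0, index=list(sequences), columns=names, dtype=int)
    for pid, seq in sequences.items():
        for m in motifs:
            counts.loc[pid, m.name] = scan_promoter(seq, m, strands)
            npos.loc[pid, m.name] = max(len(seq) - len(m) + 1, 0)
    counts.index.name = npos.index.name = "promoter_id"
    return MotifCountTable(counts, npos)


def motif_enrichment(
    fg: MotifCountTable,
    bg: MotifCountTable,
    mode: str = "promoter_presence",
) -> pd.DataFrame:
    """Per-motif foreground-vs-background over-representation.

    ``promoter_presence``: hypergeometric test on promoters containing at
    least one occurrence, with the universe being the union of foreground
    and background promoters (which must have distinct ids); the effect is
    the observed/expected ratio.

    ``occurrence_rate``: one-sided binomial test of total foreground
    occurrences against the background per-position occurrence rate; the
    effect is the foreground/background rate ratio.
    """
    if fg.counts.empty or bg.counts.empty:
        raise ValueError("foreground and background must be nonempty")
    motifs = list(fg.counts.columns)
    if list(bg.counts.columns) != motifs:
        raise ValueError("foreground and background motif columns differ")
    rows = []
    for name in motifs:
        if mode == "promoter_presence":
            fg_ids = set(fg.counts.index)
            bg_ids = set(bg.counts.index)
            if fg_ids & bg_ids:
                raise ValueError(
                    "promoter_presence mode needs disjoint fg/bg promoter ids"
                )
            universe = fg_ids | bg_ids
            category = fg.presence(name) | bg.presence(name)
            res = _enrichment.enrichment_test(fg_ids, category, universe)
            rows.append(
                {
                    "motif": name,
                    "p_value": res.p_over,
                    "effect": res.ratio,
                    "fg_hits": len(fg.presence(name)),
                    "bg_hits": len(bg.presence(name)),
                }
            )
        elif mode == "occurrence_rate":
            k = int(fg.counts[name].sum())
            n = int(fg.n_positions[name].sum())
            bg_k = int(bg.counts[name].sum())
            bg_n = int(bg.n_positions[name].sum())
            if bg_n == 0 or n == 0:
                raise ValueError("empty scannable positions")
            # add-one smoothing keeps the null rate defined when the
            # background has zero occurrences
            rate0 = min((bg_k + 1) / (bg_n + 1), 1.0)
            p = stats.binomtest(k, n, rate0, alternative="greater").pvalue
            fg_rate = k / n
            bg_rate = bg_k / bg_n
            rows.append(
                {
                    "motif": name,
                    "p_value": float(p),
                    "effect": fg_rate / bg_rate if bg_rate > 0 else np.inf,
                    "fg_hits": k,
                    "bg_hits": bg_k,
                }
            )
        else:
            raise ValueError("mode must be 'promoter_presence' or 'occurrence_rate'")
    return pd.DataFrame(rows).set_index("motif")


class MotifScanner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: promoter sequences -> motif count matrix.

    ``transform`` accepts a dict id -> sequence or a list of sequences and
    returns the counts DataFrame; the full :class:`MotifCountTable` of the
    last transform is kept on ``table_``.
    """

    def __init__(
        self,
        motifs: tuple[Motif, ...] = DEFAULT_MOTIFS,
        strands: str = "both",
    ):
        self.motifs = motifs
        self.strands = strands

    def fit(self, X=None, y=None) -> "MotifScanner":
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, dict):
            X = {f"seq_{i}": s for i, s in enumerate(X)}
        self.table_ = scan_promoters(X, self.motifs, self.strands)
        return self.table_.counts


def read_motif_library(path: str | Path) -> tuple[Motif, ...]:
    """Read a two-column (name TAB consensus) motif library file."""
    motifs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, iupac = line.split("\t")[:2]
        motifs.append(Motif(name, iupac))
    return tuple(motifs)


def write_motif_library(motifs: tuple[Motif, ...], path: str | Path) -> None:
    Path(path).write_text("".join(f"{m.name}\t{m.iupac}\n" for m in motifs))


def read_promoters_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
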