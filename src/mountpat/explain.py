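"""Directed-Lobish (DLob) symbolic explanations of selected features.

Every feature index of the extractor encodes a (transform map, source
channel, destination channel) triple — one cell of one rank-transition
table.  Decoding the indices chosen by the selector and mapping channels
onto a small alphabet of lobe symbols (frontal / temporal / central /
parietal / occipital / auditory, each left / right / midline — Directed
Lobish) turns a feature subset into a readable "sentence" over brain
regions.  Collapsing each symbol to its hemisphere (L / R / M) gives a
coarser hemispheric sentence.  Histograms, transition tables, Shannon
entropy and the complexity ratio (entropy as a percentage of the alphabet
maximum ``log2 S``) summarise which regions — and which region-to-region
transitions — drive the classification.

These statistics describe where discriminative features live; they are not
functional-connectivity or neurophysiological activation measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import n_output_maps
from .select import SelectionResult

__all__ = [
    "DLOB_ALPHABET",
    "HEMISPHERES",
    "EMOTIV_14_MONTAGE",
    "STANDARD_32_MONTAGE",
    "SymbolMap",
    "SymbolSentence",
    "SymbolStats",
    "decode_feature_index",
    "generate_sentences",
    "complexity_ratio",
    "symbol_stats",
    "activation_report",
]

# The 16-symbol directed lobe alphabet: first letter = lobe/area, second =
# direction (L left, R right, z midline).
DLOB_ALPHABET = (
    "FR", "FL", "Fz", "TL", "TR", "CL", "CR", "Cz",
    "PL", "PR", "Pz", "OL", "OR", "Oz", "AL", "AR",
)
HEMISPHERES = ("L", "R", "M")

# Common 14-channel consumer headset montage; its active alphabet has
# 8 lateral lobe symbols and 2 hemispheric symbols.
EMOTIV_14_MONTAGE: dict[str, str] = {
    "AF3": "FL", "F7": "FL", "F3": "FL", "FC5": "FL", "T7": "TL",
    "P7": "PL", "O1": "OL", "O2": "OR", "P8": "PR", "T8": "TR",
    "FC6": "FR", "F4": "FR", "F8": "FR", "AF4": "FR",
}

# Typical 32-channel 10-20 layout; active alphabet: 14 lobe symbols
# (midline electrodes present), 3 hemispheric symbols.
STANDARD_32_MONTAGE: dict[str, str] = {
    "Fp1": "FL", "Fp2": "FR", "F7": "FL", "F3": "FL", "Fz": "Fz",
    "F4": "FR", "F8": "FR", "FC5": "CL", "FC1": "CL", "FC2": "CR",
    "FC6": "CR", "T7": "TL", "C3": "CL", "Cz": "Cz", "C4": "CR",
    "T8": "TR", "TP9": "TL", "CP5": "PL", "CP1": "PL", "CP2": "PR",
    "CP6": "PR", "TP10": "TR", "P7": "PL", "P3": "PL", "Pz": "Pz",
    "P4": "PR", "P8": "PR", "PO9": "OL", "O1": "OL", "Oz": "Oz",
    "O2": "OR", "PO10": "OR",
}


def _hemisphere(symbol: str) -> str:
    return "M" if symbol.endswith("z") else symbol[-1]


@dataclass
class SymbolMap:
    """Electrode -> lobe-symbol mapping for one montage.

    The hemisphere map is derived from each symbol's direction letter
    (L -> L, R -> R, z -> M).  Load custom montages from JSON files of the
    form ``{"channel": "symbol", ...}``.
    """

    channel_to_symbol: dict[str, str]
    symbol_to_hemisphere: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        for ch, sym in self.channel_to_symbol.items():
            if sym not in DLOB_ALPHABET:
                raise ValueError(
                    f"channel {ch!r} maps to unknown symbol {sym!r}; "
                    f"valid symbols: {DLOB_ALPHABET}"
                )
        self.symbol_to_hemisphere = {
            sym: _hemisphere(sym) for sym in set(self.channel_to_symbol.values())
        }

    @property
    def active_alphabet(self) -> list[str]:
        """Montage's lobe symbols, in canonical alphabet order."""
        used = set(self.channel_to_symbol.values())
        return [s for s in DLOB_ALPHABET if s in used]

    @property
    def active_hemispheres(self) -> list[str]:
        used = set(self.symbol_to_hemisphere.values())
        return [h for h in HEMISPHERES if h in used]

    def symbol(self, channel: str) -> str:
        try:
            return self.channel_to_symbol[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel!r} is not mapped in the montage; "
                f"mapped channels: {sorted(self.channel_to_symbol)}"
            ) from None

    @classmethod
    def from_json(cls, path: str | Path) -> "SymbolMap":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.channel_to_symbol, fh, indent=1)


@dataclass
class SymbolSentence:
    """Ordered symbol sequence over a fixed alphabet."""

    symbols: list[str]
    alphabet: list[str]

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(self.alphabet)
        if bad:
            raise ValueError(f"symbols {sorted(bad)} outside alphabet {self.alphabet}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class SymbolStats:
    """Histogram, transitions and entropy summary of a symbol sentence."""

    histogram: pd.Series
    transition_table: pd.DataFrame
    entropy_bits: float
    complexity_ratio_pct: float


def decode_feature_index(z: int, nc: int, n: int = 5) -> tuple[int, int, int]:
    """Invert the flatten+concatenate layout of the extractor.

    Maps a 1-based feature index ``z`` to ``(u, a, b)``: transform map
    ``u`` in ``1..n+C(n,2)``, source channel ``a`` and destination channel
    ``b`` (both 1-based) of the transition-table cell the feature counts.
    """
    R = n_output_maps(n)
    if not 1 <= z <= R * nc * nc:
        raise ValueError(f"feature index {z} outside [1, {R * nc * nc}]")
    z0 = z - 1
    u, rem = divmod(z0, nc * nc)
    a, b = divmod(rem, nc)
    return u + 1, a + 1, b + 1


def generate_sentences(
    selection: SelectionResult | list[int],
    channel_labels: list[str],
    symbol_map: SymbolMap,
    n: int = 5,
) -> tuple[SymbolSentence, SymbolSentence]:
    """DLob and hemispheric sentences from the selected feature indices.

    Selected features are visited in descending-weight order; each decodes
    to a (map, source channel, destination channel) triple and contributes
    its source symbol then its destination symbol, so ``k`` selected
    features yield a sentence of length ``2k``.
    """
    indices = selection.selected if isinstance(selection, SelectionResult) else selection
    if not indices:
        raise ValueError("empty selection: nothing to explain")
    nc = len(channel_labels)
    for ch in channel_labels:
        symbol_map.symbol(ch)  # fail early, naming the unmapped channel
    dlob: list[str] = []
    for z in indices:
        _, a, b = decode_feature_index(int(z), nc, n)
        dlob.append(symbol_map.symbol(channel_labels[a - 1]))
        dlob.append(symbol_map.symbol(channel_labels[b - 1]))
    hemi = [symbol_map.symbol_to_hemisphere[s] for s in dlob]
    return (
        SymbolSentence(dlob, symbol_map.active_alphabet),
        SymbolSentence(hemi, symbol_map.active_hemispheres),
    )


def complexity_ratio(entropy_bits: float, alphabet_size: int) -> float:
    """Entropy as a percentage of the alphabet maximum ``log2(S)``.

    A single-symbol alphabet has zero capacity; its ratio is defined as 0.
    """
    if alphabet_size < 1:
        raise ValueError("alphabet size must be >= 1")
    if alphabet_size == 1:
        return 0.0
    return 100.0 * entropy_bits / np.log2(alphabet_size)


def symbol_stats(sentence: SymbolSentence) -> SymbolStats:
    """Histogram, transition table, Shannon entropy and complexity ratio.

    Entropy is ``-sum p log2 p`` over the empirical symbol frequencies
    (zero-count symbols contribute nothing); the complexity ratio
    normalises by ``log2`` of the alphabet size.
    """
    if len(sentence) == 0:
        raise ValueError("empty sentence")
    alphabet = sentence.alphabet
    hist = pd.Series(0, index=alphabet, dtype=int)
    for s in sentence.symbols:
        hist[s] += 1
    p = hist[hist > 0] / hist.sum()
    H = float(-(p * np.log2(p)).sum())
    tt = pd.DataFrame(0, index=alphabet, columns=alphabet, dtype=int)
    for a, b in zip(sentence.symbols[:-1], sentence.symbols[1:]):
        tt.loc[a, b] += 1
    return SymbolStats(
        histogram=hist,
        transition_table=tt,
        entropy_bits=H,
        complexity_ratio_pct=complexity_ratio(H, len(alphabet)),
    )


def activation_report(
    dlob_stats: SymbolStats, hemi_stats: SymbolStats
) -> tuple[str, pd.DataFrame]:
    """Ranked symbol frequencies and transition edge list, as text + table.

    Returns the human-readable report and a machine-readable edge list
    (``symbol_from, symbol_to, count``) sorted by descending count, ties
    broken lexicographically.  Edge counts sum to sentence length - 1.
    """
    def _edges(tt: pd.DataFrame) -> pd.DataFrame:
        rows = [
            (a, b, int(tt.loc[a, b]))
            for a in tt.index
            for b in tt.columns
            if tt.loc[a, b] > 0
        ]
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        return pd.DataFrame(rows, columns=["symbol_from", "symbol_to", "count"])

    def _ranked(hist: pd.Series) -> list[tuple[str, int]]:
        items = [(s, int(c)) for s, c in hist.items() if c > 0]
        items.sort(key=lambda r: (-r[1], r[0]))
        return items

    lines = ["Lobe-symbol activation report", "=" * 29, ""]
    for name, stats in (("DLob", dlob_stats), ("Hemispheric", hemi_stats)):
        lines.append(f"{name} sentence")
        lines.append(
            f"  entropy: {stats.entropy_bits:.4f} bits  "
            f"complexity ratio: {stats.complexity_ratio_pct:.2f}%"
        )
        lines.append("  symbol frequencies (descending):")
        for sym, c in _ranked(stats.histogram):
            lines.append(f"    {sym:<3} {c}")
        edges = _edges(stats.transition_table)
        lines.append("  top transitions:")
        for _, row in edges.head(10).iterrows():
            lines.append(
                f"    {row.symbol_from} -> {row.symbol_to}  {row['count']}"
            )
        lines.append("")
    dlob_edges = _edges(dlob_stats.transition_table)
    return "\n".join(lines), dlob_edges
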