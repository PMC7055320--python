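"""Genomic track containers for per-CpG deamination counts and methylation.

Two thin wrappers around :class:`pandas.DataFrame` carry all per-CpG data in
the package:

* :class:`CpGCountTrack` — the raw substrate of ancient-DNA methylation
  reconstruction: at every CpG, the number of reads carrying a C (``c``) and
  the number carrying a T (``t``).  Post-mortem deamination converts
  methylated cytosines into thymines, so ``t / (c + t)`` encodes methylation.
* :class:`MethylationTrack` — a per-CpG methylation fraction in [0, 1],
  either measured (WGBS, arrays) or reconstructed from counts.

Coordinates are 0-based and strictly increasing within each chromosome.
On disk, counts are TSV (chrom, pos, c_count, t_count) and methylation is
bedGraph (chrom, start, start+1, value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CpGCountTrack", "MethylationTrack", "intersect_positions"]


def _check_sorted(df: pd.DataFrame) -> None:
    for _, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing per chromosome")


class CpGCountTrack:
    """Per-CpG deamination evidence (C and T read counts) for one sample.

    Parameters
    ----------
    df : DataFrame with columns ``chrom``, ``pos``, ``c``, ``t``; optional
        auxiliary columns ``ag`` (A+G read sum at the site) and ``ga_ratio``
        (opposite-strand G→A ratio) feed the pre-mortem mutation filters.
    meta : free-form sample metadata (``sample_id``, ``library`` in
        {"single", "double"}, ``pi`` when known, ...).
    """

    required = ("chrom", "pos", "c", "t")

    def __init__(self, df: pd.DataFrame, meta: dict | None = None, validate: bool = True):
        df = df.reset_index(drop=True)
        for col in self.required:
            if col not in df.columns:
                raise ValueError(f"count track missing column {col!r}")
        if validate:
            if (df["c"] < 0).any() or (df["t"] < 0).any():
                raise ValueError("negative counts")
            _check_sorted(df)
        self.df = df
        self.meta = dict(meta or {})

    @property
    def n(self) -> np.ndarray:
        """Per-site coverage n_i = c_i + t_i."""
        return (self.df["c"] + self.df["t"]).to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        sid = self.meta.get("sample_id", "?")
        return f"<CpGCountTrack sample={sid} sites={len(self)}>"

    def to_tsv(self, path) -> None:
        out = self.df.rename(columns={"c": "c_count", "t": "t_count"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, meta: dict | None = None) -> "CpGCountTrack":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={"c_count": "c", "t_count": "t"})
        return cls(df, meta=meta)


class MethylationTrack:
    """Per-CpG methylation fraction in [0, 1].

    ``smoothing_window`` records the CpG window the values were pooled over
    (1 = unsmoothed).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        smoothing_window: int = 1,
        meta: dict | None = None,
        validate: bool = True,
    ):
        df = df.reset_index(drop=True)
        for col in ("chrom", "pos", "methylation"):
            if col not in df.columns:
                raise ValueError(f"methylation track missing column {col!r}")
        if validate:
            vals = df["methylation"].to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation outside [0, 1]")
            _check_sorted(df)
        self.df = df
        self.smoothing_window = int(smoothing_window)
        self.meta = dict(meta or {})

    @property
    def values(self) -> np.ndarray:
        return self.df["methylation"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        sid = self.meta.get("sample_id", "?")
        return (
            f"<MethylationTrack sample={sid} sites={len(self)} "
            f"window={self.smoothing_window}>"
        )

    def to_bedgraph(self, path) -> None:
        out = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "start": self.df["pos"],
                "end": self.df["pos"] + 1,
                "value": self.df["methylation"],
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bedgraph(cls, path, smoothing_window: int = 1, meta: dict | None = None):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        df = pd.DataFrame(
            {"chrom": df["chrom"], "pos": df["start"], "methylation": df["value"]}
        )
        return cls(df, smoothing_window=smoothing_window, meta=meta)


def intersect_positions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two per-CpG tables on (chrom, pos), preserving order."""
    merged = a.merge(b, on=["chrom", "pos"], how="inner", suffixes=("_a", "_b"))
    return merged
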