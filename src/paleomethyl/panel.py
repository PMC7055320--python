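"""Sample panels: who was measured, how, and with which track.

A :class:`SamplePanel` is the roster a comparative analysis runs over.  Each
:class:`Sample` carries its group (AMH / Neanderthal / Denisovan /
chimpanzee), tissue, sex, age class and measurement technology, plus the
track(s) backing it: deamination counts for reconstructed ancient samples,
a methylation track for WGBS/RRBS/array samples.  Technology drives the
filtering logic downstream — array samples only enter the strict
variability-filtering mode, low-coverage samples get a wider smoothing
window, and the outgroup is the chimpanzee used for lineage polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tracks import CpGCountTrack, MethylationTrack

HOMININ_GROUPS = ("AMH", "Neanderthal", "Denisovan")
OUTGROUP = "chimpanzee"
TECHNOLOGIES = ("reconstructed", "WGBS", "RRBS", "array450K", "array850K")
ARRAY_TECHNOLOGIES = ("array450K", "array850K")


@dataclass
class Sample:
    id: str
    group: str
    tissue: str = "bone"
    sex: str = "U"
    age_class: str = "adult"
    technology: str = "reconstructed"
    counts: CpGCountTrack | None = None
    methylation: MethylationTrack | None = None
    pi: float | None = None           # deamination rate, if known/estimated
    window: int | None = None         # per-sample smoothing override (e.g. low coverage)

    def __post_init__(self):
        if self.technology not in TECHNOLOGIES:
            raise ValueError(f"unknown technology {self.technology!r}")

    @property
    def is_array(self) -> bool:
        return self.technology in ARRAY_TECHNOLOGIES


@dataclass
class SamplePanel:
    samples: list[Sample] = field(default_factory=list)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def by_group(self, group: str) -> list[Sample]:
        return [s for s in self.samples if s.group == group]

    def get(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def core_samples(self) -> dict[str, Sample]:
        """One reconstructed (deamination-count) sample per hominin group.

        These are the samples the pairwise detector runs on; the first
        reconstructed sample listed per group is taken.
        """
        core: dict[str, Sample] = {}
        for s in self.samples:
            if s.group in HOMININ_GROUPS and s.technology == "reconstructed":
                core.setdefault(s.group, s)
        return core

    def outgroup_sample(self, technology: str = "WGBS") -> Sample | None:
        for s in self.samples:
            if s.group == OUTGROUP and s.technology == technology:
                return s
        return None

    def to_manifest(self, path, track_dir=None) -> None:
        """Write a TSV manifest (id, group, tissue, sex, age, technology, path)."""
        rows = []
        track_dir = Path(track_dir) if track_dir else Path(path).parent
        for s in self.samples:
            if s.counts is not None:
                fname = f"{s.id}.counts.tsv"
                s.counts.to_tsv(track_dir / fname)
            elif s.methylation is not None:
                fname = f"{s.id}.meth.bedgraph"
                s.methylation.to_bedgraph(track_dir / fname)
            else:
                fname = ""
            rows.append(
                dict(id=s.id, group=s.group, tissue=s.tissue, sex=s.sex,
                     age=s.age_class, technology=s.technology, path=fname)
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_manifest(cls, path) -> "SamplePanel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        samples = []
        for _, row in df.iterrows():
            s = Sample(
                id=row["id"], group=row["group"], tissue=row.get("tissue", "bone"),
                sex=row.get("sex", "U"), age_class=row.get("age", "adult"),
                technology=row["technology"],
            )
            track_path = path.parent / str(row["path"])
            if str(row["path"]):
                if s.technology == "reconstructed":
                    s.counts = CpGCountTrack.from_tsv(track_path, meta={"sample_id": s.id})
                else:
                    s.methylation = MethylationTrack.from_bedgraph(
                        track_path, meta={"sample_id": s.id}
                    )
            samples.append(s)
        return cls(samples)
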