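"""The soil OTU table: read counts per sample plus representatives and metadata."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .sequences import SequenceRecord, load_inventory, write_fasta


@dataclass
class OtuTable:
    """OTU-by-sample integer read counts with representative sequences.

    ``counts`` is indexed by otu_id with one column per sample_id;
    ``rep_seqs`` maps otu_id to its representative sequence; ``samples`` is
    indexed by sample_id with columns site, elevation_m and canopy (op/cl).
    """

    counts: pd.DataFrame
    rep_seqs: dict[str, str]
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.rep_seqs)
        if missing:
            raise FormatError(f"OTUs without representative sequence: {sorted(missing)[:5]} ...")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative read counts")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def reads_per_otu(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def reads_per_sample(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def otus_per_sample(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    def rep_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=o, sequence=self.rep_seqs[o], source="soil",
                           abundance=max(1, int(self.counts.loc[o].sum())))
            for o in self.counts.index
        ]

    # ---------------------------------------------------------------- I/O
    def write(self, table_path: str | Path, fasta_path: str | Path,
              samples_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(table_path, sep="\t")
        write_fasta(self.rep_records(), fasta_path)
        if samples_path is not None and not self.samples.empty:
            sm = self.samples.copy()
            sm.index.name = "sample_id"
            sm.to_csv(samples_path, sep="\t")

    @classmethod
    def read(cls, table_path: str | Path, fasta_path: str | Path,
             samples_path: str | Path | None = None) -> "OtuTable":
        counts = pd.read_csv(table_path, sep="\t", index_col="otu_id")
        reps = {r.id: r.sequence for r in load_inventory(fasta_path, source="soil")}
        samples = pd.DataFrame()
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts=counts.astype(int), rep_seqs=reps, samples=samples)
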