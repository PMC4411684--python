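"""Multiple-sequence-alignment container shared by the profile and tree stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = "-."


@dataclass
class MSA:
    """Gapped alignment: ordered mapping of sequence id to aligned row."""

    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_id: str) -> str:
        row = self.rows[seq_id]
        return "".join(c for c in row if c not in GAP_CHARS)

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows.values())

    def select_columns(self, idx) -> "MSA":
        return MSA({k: "".join(v[i] for i in idx) for k, v in self.rows.items()})

    def drop_gappy_columns(self, max_gap_frac: float = 0.5) -> "MSA":
        """Drop columns where more than ``max_gap_frac`` of rows are gaps."""
        n = self.n_rows
        keep = [i for i in range(self.length)
                if sum(1 for c in self.column(i) if c in GAP_CHARS) <= max_gap_frac * n]
        return self.select_columns(keep)

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")})

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(row), id=k, description="")
                   for k, row in self.rows.items()]
        SeqIO.write(records, path, "fasta")
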