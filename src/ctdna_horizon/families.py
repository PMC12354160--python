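"""Duplex read-family containers.

A duplex family is one original cfDNA template molecule, identified by its
UID, with read observations from both the Watson and Crick strands. Two
representations are provided:

* :class:`DuplexFamily` — an object per molecule, convenient for unit-level
  reasoning and the per-family operations;
* :class:`FamilyTable` — a columnar container (one row per family x site,
  base counts per strand) that the vectorised consensus caller operates on.
  This is the in-memory form of the families TSV.

The TSV format is long: ``uid  chrom  pos  strand  base  reads`` with one
row per observed base per strand (zero-count bases omitted).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the base-count matrices
BASE_ORDER = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
STRANDS = ("W", "C")

TSV_COLUMNS = ["uid", "chrom", "pos", "strand", "base", "reads"]


@dataclass
class DuplexFamily:
    """One template molecule: per-site Watson and Crick base observations."""

    uid: int
    watson: dict[tuple[str, int], Counter] = field(default_factory=dict)
    crick: dict[tuple[str, int], Counter] = field(default_factory=dict)

    @property
    def sites(self) -> set[tuple[str, int]]:
        return set(self.watson) | set(self.crick)

    def covers(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.sites

    def reads(self, strand: str, chrom: str, pos: int) -> Counter:
        if strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        store = self.watson if strand == "W" else self.crick
        return store.get((chrom, pos), Counter())


class FamilyTable:
    """Columnar duplex families: one row per (family, site).

    Attributes
    ----------
    uid, chrom, pos : arrays of length n_rows
    watson, crick : (n_rows, 5) int arrays of read counts over A,C,G,T,N
    """

    def __init__(
        self,
        uid: np.ndarray,
        chrom: np.ndarray,
        pos: np.ndarray,
        watson: np.ndarray,
        crick: np.ndarray,
    ) -> None:
        n = len(uid)
        uid = np.asarray(uid, dtype=np.int64)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        watson = np.asarray(watson, dtype=np.int32)
        crick = np.asarray(crick, dtype=np.int32)
        if not (len(chrom) == len(pos) == n and watson.shape == crick.shape == (n, 5)):
            raise ValueError("inconsistent FamilyTable array shapes")
        if (watson < 0).any() or (crick < 0).any():
            raise ValueError("negative read counts")
        self.uid = uid
        self.chrom = chrom
        self.pos = pos
        self.watson = watson
        self.crick = crick

    def __len__(self) -> int:
        return len(self.uid)

    @property
    def n_families(self) -> int:
        return len(np.unique(self.uid))

    def site_keys(self) -> list[tuple[str, int]]:
        seen = dict.fromkeys(zip(self.chrom.tolist(), self.pos.tolist()))
        return list(seen)

    def restrict(self, chrom: str, pos: int) -> "FamilyTable":
        mask = (self.chrom == chrom) & (self.pos == pos)
        return FamilyTable(
            self.uid[mask], self.chrom[mask], self.pos[mask],
            self.watson[mask], self.crick[mask],
        )

    @classmethod
    def concat(cls, tables: list["FamilyTable"]) -> "FamilyTable":
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([t.uid for t in tables]),
            np.concatenate([t.chrom for t in tables]),
            np.concatenate([t.pos for t in tables]),
            np.vstack([t.watson for t in tables]),
            np.vstack([t.crick for t in tables]),
        )

    @classmethod
    def empty(cls) -> "FamilyTable":
        return cls(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty((0, 5), dtype=np.int32),
            np.empty((0, 5), dtype=np.int32),
        )

    # -- conversions ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (``uid chrom pos strand base reads``)."""
        frames = []
        for strand, counts in (("W", self.watson), ("C", self.crick)):
            rows, cols = np.nonzero(counts)
            frames.append(
                pd.DataFrame(
                    {
                        "uid": self.uid[rows],
                        "chrom": self.chrom[rows],
                        "pos": self.pos[rows],
                        "strand": strand,
                        "base": np.array(list(BASE_ORDER), dtype=object)[cols],
                        "reads": counts[rows, cols],
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(
            ["uid", "chrom", "pos", "strand", "base"], kind="stable"
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FamilyTable":
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"families frame missing columns {missing}")
        if len(df) == 0:
            return cls.empty()
        bad = ~df["base"].isin(list(BASE_ORDER))
        if bad.any():
            raise ValueError(f"invalid base(s): {sorted(df.loc[bad, 'base'].unique())}")
        key = pd.MultiIndex.from_frame(df[["uid", "chrom", "pos"]])
        uniq, inverse = np.unique(key, return_inverse=True)
        n = len(uniq)
        watson = np.zeros((n, 5), dtype=np.int32)
        crick = np.zeros((n, 5), dtype=np.int32)
        base_idx = df["base"].map(BASE_INDEX).to_numpy()
        reads = df["reads"].to_numpy(dtype=np.int64)
        is_w = (df["strand"] == "W").to_numpy()
        np.add.at(watson, (inverse[is_w], base_idx[is_w]), reads[is_w])
        np.add.at(crick, (inverse[~is_w], base_idx[~is_w]), reads[~is_w])
        uids = np.array([u for u, _, _ in uniq], dtype=np.int64)
        chroms = np.array([c for _, c, _ in uniq], dtype=object)
        poss = np.array([p for _, _, p in uniq], dtype=np.int64)
        return cls(uids, chroms, poss, watson, crick)

    def to_families(self) -> list[DuplexFamily]:
        """Expand into per-molecule objects (small inputs only)."""
        out: dict[int, DuplexFamily] = {}
        for i in range(len(self)):
            fam = out.setdefault(int(self.uid[i]), DuplexFamily(int(self.uid[i])))
            key = (str(self.chrom[i]), int(self.pos[i]))
            w = Counter({b: int(c) for b, c in zip(BASE_ORDER, self.watson[i]) if c})
            c = Counter({b: int(n) for b, n in zip(BASE_ORDER, self.crick[i]) if n})
            if w:
                fam.watson[key] = fam.watson.get(key, Counter()) + w
            if c:
                fam.crick[key] = fam.crick.get(key, Counter()) + c
        return list(out.values())

    @classmethod
    def from_families(cls, families: list[DuplexFamily]) -> "FamilyTable":
        rows = []
        for fam in families:
            for key in sorted(fam.sites):
                w = np.zeros(5, dtype=np.int32)
                c = np.zeros(5, dtype=np.int32)
                for b, n in fam.watson.get(key, {}).items():
                    w[BASE_INDEX[b]] += n
                for b, n in fam.crick.get(key, {}).items():
                    c[BASE_INDEX[b]] += n
                rows.append((fam.uid, key[0], key[1], w, c))
        if not rows:
            return cls.empty()
        return cls(
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=object),
            np.array([r[2] for r in rows], dtype=np.int64),
            np.vstack([r[3] for r in rows]),
            np.vstack([r[4] for r in rows]),
        )
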