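"""Reading, validating and writing diploid microsatellite genotype matrices.

The central container is :class:`GenotypeMatrix`: N sampling units x L loci of
unordered diploid allele-size pairs, with one population label per sample.
Two on-disk dialects are supported: the classic genepop format (2- or 3-digit
allele encoding, auto-detected on read, 3-digit on write) and a long-form TSV
(sample, pop, locus, allele1, allele2) for debuggability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing allele call (both slots set when a genotype is missing)
MISSING = -1


class GenepopParseError(ValueError):
    """Raised when a genepop file violates the dialect."""


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotypes for N samples x L loci.

    calls[i, l] is an unordered pair of positive integer allele sizes, stored
    sorted ascending; a missing genotype has both entries equal to MISSING.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    loci: list[str]
    calls: np.ndarray  # (N, L, 2) int32
    ploidy: int = 2
    encoding_digits: int = 3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {L} loci x 2"
            )
        if len(self.pop_labels) != n:
            raise ValueError("one population label required per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if n == 0 or L == 0:
            raise ValueError("empty genotype matrix")
        # canonicalize: unordered pairs stored sorted; partial missing -> missing
        self.calls = np.sort(self.calls, axis=2)
        partial = (self.calls <= 0).any(axis=2)
        self.calls[partial] = MISSING
        valid = self.calls[~partial]
        if valid.size and (valid <= 0).any():
            raise ValueError("allele sizes must be positive integers")
        self.pop_labels = list(self.pop_labels)
        self.sample_ids = list(self.sample_ids)
        self.loci = list(self.loci)

    # -- basic queries ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.pop_labels], dtype=bool)

    def missing_mask(self) -> np.ndarray:
        """(N, L) boolean, True where the genotype call is missing."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, sample_idx: np.ndarray) -> "GenotypeMatrix":
        sample_idx = np.asarray(sample_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            pop_labels=[self.pop_labels[i] for i in sample_idx],
            loci=list(self.loci),
            calls=self.calls[sample_idx].copy(),
            encoding_digits=self.encoding_digits,
        )

    def equal_calls(self, other: "GenotypeMatrix") -> bool:
        """True if sample/locus structure and all (unordered) calls match."""
        return (
            self.sample_ids == other.sample_ids
            and self.pop_labels == other.pop_labels
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# genepop dialect
# ---------------------------------------------------------------------------


def _parse_genotype_token(tok: str, line_no: int) -> tuple[int, tuple[int, int]]:
    """Return (digits, (a1, a2)) for one genotype token like '001002' or '0102'."""
    if not tok.isdigit() or len(tok) not in (4, 6):
        raise GenepopParseError(
            f"line {line_no}: genotype token {tok!r} is not 4 or 6 digits"
        )
    d = len(tok) // 2
    return d, (int(tok[:d]), int(tok[d:]))


def read_genepop(path) -> GenotypeMatrix:
    """Read a genepop file into a GenotypeMatrix.

    Accepts 2- and 3-digit allele encodings (auto-detected, must be consistent
    within the file), locus names one per line or comma-separated, and the
    usual '00'/'000' missing code. Populations are numbered Pop1, Pop2, ... in
    file order unless a sample id carries a recognisable label (the id before
    the comma is kept verbatim as the sample id; the population label is the
    id of the *last* sample in the block, the genepop convention being that
    blocks are anonymous — we instead label blocks Pop1.. for stability and
    store the raw ids).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("empty file")
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw)]
    # title line is lines[0]; locus names until first 'pop'
    title = lines[0][1]
    loci: list[str] = []
    i = 1
    pop_re = re.compile(r"^pop\s*$", re.IGNORECASE)
    while i < len(lines) and not pop_re.match(lines[i][1]):
        ln = lines[i][1]
        if ln:
            if "," in ln:
                loci.extend(x.strip() for x in ln.split(",") if x.strip())
            else:
                loci.append(ln)
        i += 1
    if not loci:
        raise GenepopParseError("no locus names before first 'Pop'")
    if i >= len(lines):
        raise GenepopParseError("no 'Pop' separator found")

    sample_ids: list[str] = []
    pop_labels: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digits: int | None = None
    pop_no = 0
    while i < len(lines):
        line_no, ln = lines[i]
        if pop_re.match(ln):
            pop_no += 1
            i += 1
            continue
        if not ln:
            i += 1
            continue
        if "," not in ln:
            raise GenepopParseError(f"line {line_no}: expected 'id , genotypes'")
        sid, geno = ln.split(",", 1)
        sid = sid.strip()
        toks = geno.split()
        if len(toks) != len(loci):
            raise GenepopParseError(
                f"line {line_no}: {len(toks)} genotypes for {len(loci)} loci"
            )
        calls = []
        for tok in toks:
            d, pair = _parse_genotype_token(tok, line_no)
            if digits is None:
                digits = d
            elif d != digits:
                raise GenepopParseError(
                    f"line {line_no}: mixed {d}- and {digits}-digit encodings"
                )
            calls.append(pair)
        sample_ids.append(sid)
        pop_labels.append(f"Pop{pop_no}")
        rows.append(calls)
        i += 1
    if pop_no == 0 or not rows:
        raise GenepopParseError("no populations / samples found")
    calls_arr = np.array(rows, dtype=np.int32)
    calls_arr[calls_arr == 0] = MISSING
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        loci=loci,
        calls=calls_arr,
        encoding_digits=digits or 3,
        metadata={"title": title},
    )
    return gm


def write_genepop(gm: GenotypeMatrix, path, title: str | None = None) -> None:
    """Write a GenotypeMatrix as a genepop file (3-digit encoding)."""
    if (gm.calls > 999).any():
        raise ValueError("allele size > 999 cannot be encoded in 3 digits")
    out = [title or gm.metadata.get("title", "msatpop export")]
    out.extend(gm.loci)
    pops = gm.populations
    for pop in pops:
        out.append("Pop")
        for i in np.flatnonzero(gm.pop_mask(pop)):
            toks = []
            for l in range(gm.n_loci):
                a, b = gm.calls[i, l]
                if a == MISSING:
                    a = b = 0
                toks.append(f"{a:03d}{b:03d}")
            out.append(f"{gm.sample_ids[i]} , " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TSV sidecar format
# ---------------------------------------------------------------------------


def read_tsv(path) -> GenotypeMatrix:
    """Read the long-form TSV dialect (sample, pop, locus, allele1, allele2)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "pop": str, "locus": str})
    loci = list(dict.fromkeys(df["locus"]))
    samples = list(dict.fromkeys(df["sample"]))
    pop_of = dict(zip(df["sample"], df["pop"]))
    sidx = {s: i for i, s in enumerate(samples)}
    lidx = {l: i for i, l in enumerate(loci)}
    calls = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int32)
    for s, l, a1, a2 in zip(df["sample"], df["locus"], df["allele1"], df["allele2"]):
        calls[sidx[s], lidx[l]] = (int(a1), int(a2))
    return GenotypeMatrix(
        sample_ids=samples,
        pop_labels=[pop_of[s] for s in samples],
        loci=loci,
        calls=calls,
    )


def write_tsv(gm: GenotypeMatrix, path) -> None:
    recs = []
    for i, (sid, pop) in enumerate(zip(gm.sample_ids, gm.pop_labels)):
        for l, locus in enumerate(gm.loci):
            a, b = (int(x) for x in gm.calls[i, l])
            recs.append((sid, pop, locus, a, b))
    pd.DataFrame(
        recs, columns=["sample", "pop", "locus", "allele1", "allele2"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def pool_populations(
    gm: GenotypeMatrix,
    mapping: dict[str, str],
    drop: list[str] | None = None,
) -> GenotypeMatrix:
    """Relabel populations into groups (e.g. meadows into regional demes).

    Every population label must appear in `mapping` or in `drop`; samples of
    dropped populations are removed.
    """
    drop = set(drop or [])
    missing = [p for p in gm.populations if p not in mapping and p not in drop]
    if missing:
        raise ValueError(f"populations not covered by mapping or drop list: {missing}")
    keep = np.array([p not in drop for p in gm.pop_labels], dtype=bool)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("pooling dropped every sample")
    sub = gm.subset(idx)
    sub.pop_labels = [mapping[p] for p in sub.pop_labels]
    return sub
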