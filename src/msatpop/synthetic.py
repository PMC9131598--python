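"""Study-shaped synthetic genotype data with a known-truth ledger.

The generator emulates a 12-meadow Aegean sampling design: meadows nested in
four regional demes (N, NE, NW, CW) plus a small distant Cyprus-like meadow,
18 microsatellite loci, and realistic nuisance artifacts — null alleles
(which depress observed heterozygosity and push F_IS positive) and rare
clone pairs (near-identical multilocus genotypes). Every injected artifact
is recorded in a ledger so pipeline stages can be checked against truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .scenario import DemographicScenario, Event, PriorSpec, scenario13
from .simulate import DEFAULT_LADDER, simulate_allele_matrix

#: Table-1-shaped sampling design: (meadow label, deme, sample size)
MEADOWS = [
    ("LEM", "NE", 8),
    ("IME", "NE", 32),
    ("FAN", "N", 34),
    ("VRA", "N", 34),
    ("NKA", "N", 22),
    ("VIA", "NW", 23),
    ("AGT", "NW", 38),
    ("CHA", "NW", 9),
    ("EPA", "CW", 47),
    ("WPA", "CW", 36),
    ("MAG", "CW", 37),
    ("CYP", "CYP", 11),
]

#: deme -> regional pool for the ABC stage (Cyprus dropped there)
MEADOW_TO_DEME = {m: d for m, d, _ in MEADOWS}

#: generating parameters: published point estimates for sizes and split times,
#: with the ancestral/bottleneck size and mutation rate set so that pairwise
#: theta spans the observed range (about 0.02-0.30) and gene diversity is
#: moderate; see docs/methods.md.
TRUTH_PARAMS = {
    "Ne1": 2.67e4,
    "Ne2": 1.27e4,
    "Ne3": 9.15e3,
    "Ne4": 1.53e5,
    "Na": 5.0e4,
    "t0": 324.0,
    "t2": 1530.0,
    "t3": 9270.0,
    "NeC": 2.0e4,
    "t4": 30000.0,
}
TRUTH_MU = 1.0e-4
TRUTH_GSM_P = 0.1


def study_scenario() -> DemographicScenario:
    """scenario13 extended with a Cyprus-like deme splitting off at t4 > t3."""
    base = scenario13()
    priors = dict(base.priors)
    priors["NeC"] = PriorSpec("NeC", "log-uniform", 10, 1e7)
    priors["t4"] = PriorSpec("t4", "log-uniform", 10, 4e6)
    # CYP splits off earliest; by t4 only the N lineage is still active
    events = list(base.events) + [Event("merge", "t4", source="CYP", target="N")]
    return DemographicScenario(
        name="study_truth",
        demes=base.demes + ["CYP"],
        sizes={**base.sizes, "CYP": "NeC"},
        priors=priors,
        events=events,
        constraints=base.constraints + [("t3", "t4")],
        notes={"derived_from": "scenario13", "role": "synthetic truth"},
    )


@dataclass
class TruthBundle:
    """Clean and corrupted matrices plus the exact difference ledger."""

    scenario: DemographicScenario
    params: dict[str, float]
    clean: GenotypeMatrix
    corrupted: GenotypeMatrix
    ledger: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def clone_pairs(self) -> list[tuple[str, str]]:
        return self.ledger.get("clone_pairs", [])


def inject_null_alleles(gm: GenotypeMatrix, freq_per_locus, seed):
    """Null-allele corruption: each gene copy independently becomes null.

    null/null -> missing genotype; null/visible -> apparent homozygote for
    the visible allele. Returns (corrupted copy, ledger dict) with the
    per-locus input frequency, realized new-missing rate and change list.
    """
    freq = np.broadcast_to(np.asarray(freq_per_locus, dtype=float), (gm.n_loci,))
    if (freq < 0).any() or (freq > 0.5).any():
        raise ValueError("null-allele frequencies must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(gm)
    changes = []
    scored = (~gm.missing_mask()).sum(axis=0).astype(float)
    new_missing = np.zeros(gm.n_loci)
    for l in range(gm.n_loci):
        if freq[l] == 0:
            continue
        for i in range(gm.n_samples):
            if out.calls[i, l, 0] == MISSING:
                continue
            null = rng.random(2) < freq[l]
            if null.all():
                out.calls[i, l] = MISSING
                changes.append((i, l, "missing"))
                new_missing[l] += 1
            elif null.any():
                vis = out.calls[i, l, 1 - int(np.flatnonzero(null)[0])]
                was_het = out.calls[i, l, 0] != out.calls[i, l, 1]
                out.calls[i, l] = (vis, vis)
                if was_het:
                    changes.append((i, l, "homozygote"))
    ledger = {
        "null_freq": freq.tolist(),
        "new_missing_rate": (new_missing / np.maximum(scored, 1)).tolist(),
        "changes": changes,
    }
    return out, ledger


def inject_clones(gm: GenotypeMatrix, n_pairs: int, max_distance: int, seed):
    """Overwrite n_pairs recipients with near-copies of same-meadow donors.

    Each recipient's genotype becomes the donor's with at most max_distance
    single-allele one-step edits on distinct loci (never touching missing
    slots), so donor and recipient collapse into one multilocus lineage at
    any collapse threshold >= max_distance. Sample count is unchanged.
    """
    if n_pairs > gm.n_samples // 2:
        raise ValueError("n_pairs exceeds N/2")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(gm)
    labels = np.asarray(gm.pop_labels)
    eligible_pops = [p for p in gm.populations if (labels == p).sum() >= 2]
    pairs = []
    used: set[int] = set()
    pops = list(rng.permutation(eligible_pops))
    for k in range(n_pairs):
        pop = pops[k % len(pops)]
        idx = [i for i in np.flatnonzero(labels == pop) if i not in used]
        if len(idx) < 2:
            idx = [i for i in range(gm.n_samples) if i not in used]
        donor, recip = rng.choice(idx, size=2, replace=False)
        out.calls[recip] = out.calls[donor].copy()
        scored = np.flatnonzero(out.calls[recip, :, 0] != MISSING)
        n_edits = int(rng.integers(0, max_distance + 1)) if max_distance else 0
        n_edits = min(n_edits, scored.size)
        for l in rng.choice(scored, size=n_edits, replace=False):
            slot = int(rng.integers(2))
            step = 1 if rng.random() < 0.5 else -1
            val = out.calls[recip, l, slot] + step
            out.calls[recip, l, slot] = max(1, val)
            out.calls[recip, l] = np.sort(out.calls[recip, l])
        used.update((int(donor), int(recip)))
        pairs.append((gm.sample_ids[int(donor)], gm.sample_ids[int(recip)]))
    return out, {"clone_pairs": pairs, "max_distance": int(max_distance)}


def make_study_like(
    seed: int,
    scale: float = 1.0,
    n_loci: int = 18,
    n_clone_pairs: int = 3,
    clone_max_distance: int = 2,
    null_freq_high: float = 0.15,
    mu: float = TRUTH_MU,
    gsm_p: float = TRUTH_GSM_P,
) -> TruthBundle:
    """Generate a full study-shaped dataset with known truth.

    scale in (0, 1] shrinks every meadow (each kept >= 2 samples); scale=1
    gives the published design of 331 sampling units over 12 meadows. The
    clean matrix comes straight from the coalescent; the corrupted matrix
    adds per-locus null alleles (frequency ~ U(0, null_freq_high)) and
    n_clone_pairs near-identical clone pairs, all ledgered.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scn = study_scenario()
    meadow_sizes = [(m, d, max(2, round(n * scale))) for m, d, n in MEADOWS]
    deme_sizes: dict[str, int] = {}
    for _, d, n in meadow_sizes:
        deme_sizes[d] = deme_sizes.get(d, 0) + n
    mu_locus = rng.gamma(2.0, mu / 2.0, n_loci)
    alleles, pop_codes, code_to_name = simulate_allele_matrix(
        scn,
        TRUTH_PARAMS,
        deme_sizes,
        n_loci,
        mu_locus,
        gsm_p,
        ladder=DEFAULT_LADDER,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    # assign meadow labels as consecutive blocks within each deme
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    order = np.argsort(pop_codes, kind="stable")
    alleles = alleles[order]
    deme_of_row = np.array([code_to_name[int(c)] for c in pop_codes[order]])
    cursor = {d: 0 for d in deme_sizes}
    row_meadow = np.empty(alleles.shape[0], dtype=object)
    for m, d, n in meadow_sizes:
        rows = np.flatnonzero(deme_of_row == d)[cursor[d] : cursor[d] + n]
        cursor[d] += n
        for j, r in enumerate(rows):
            row_meadow[r] = m
    for r in range(alleles.shape[0]):
        m = row_meadow[r]
        sample_ids.append(f"{m}_{r:03d}")
        pop_labels.append(m)
    # meadow order as in the design table
    meadow_rank = {m: i for i, (m, _, _) in enumerate(meadow_sizes)}
    order2 = np.argsort([meadow_rank[m] for m in pop_labels], kind="stable")
    clean = GenotypeMatrix(
        sample_ids=[sample_ids[i] for i in order2],
        pop_labels=[pop_labels[i] for i in order2],
        loci=[f"L{l+1:02d}" for l in range(n_loci)],
        calls=alleles[order2],
    )
    null_freq = rng.uniform(0.0, null_freq_high, n_loci)
    corrupted, null_ledger = inject_null_alleles(
        clean, null_freq, seed=int(rng.integers(1, 2**31 - 1))
    )
    corrupted, clone_ledger = inject_clones(
        corrupted, n_clone_pairs, clone_max_distance,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    return TruthBundle(
        scenario=scn,
        params={**TRUTH_PARAMS, "mu_mean": mu, "gsm_p": gsm_p},
        clean=clean,
        corrupted=corrupted,
        ledger={**null_ledger, **clone_ledger,
                "meadow_to_deme": dict(MEADOW_TO_DEME)},
        seed=seed,
    )
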