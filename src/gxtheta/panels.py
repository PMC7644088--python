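"""Seeded forward simulators for two-founder mapping panels.

Three designs are covered, each yielding genotypes with known truth
(founder mosaics and global ancestry theta):

* **RI** — recombinant inbred lines: an F2 cross followed by recurrent
  brother-sister mating until every locus is fixed, giving fully homozygous
  mosaic genomes.  Mean ancestry across a neutral panel is ~0.5.
* **AIL** — advanced intercross lines: random mating for many generations
  (default 50) after the F1, accumulating recombinations while staying
  heterozygous; dosages occupy {0, 0.5, 1}.
* **haploid-cross** — haploid progeny from a single meiosis of the F1
  diploid (yeast-segregant style); dosages occupy {0, 1}.

Meiosis uses the Haldane (no-interference) map: adjacent markers separated
by d Morgans recombine with probability r = (1 - exp(-2d)) / 2, which is
exactly a Markov switching process along the chromosome.  Viability
selection at chosen loci is modeled as rejection sampling: an offspring
carrying at least one disfavored allele at a selected locus is discarded
with probability s and redrawn.

Founder A is the designated reference founder (the "common parent" of the
panel); its allele is dosage 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gxtheta.data_model import AncestryVector, GenotypeMatrix

__all__ = [
    "ChromosomeSpec",
    "PanelSpec",
    "PanelResult",
    "simulate_ri_panel",
    "simulate_ail",
    "simulate_haploid_cross",
    "founder_genotypes",
    "default_panel_spec",
]

#: physical scale used for marker coordinates (mouse-like: ~2 Mb per cM)
BP_PER_CM = 2_000_000

#: generation cap for RI fixation before residual blocks are coin-flipped
RI_FIXATION_CAP = 60

#: redraw budget per offspring under viability selection
SELECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class ChromosomeSpec:
    label: str
    length_cm: float
    n_snps: int

    def __post_init__(self):
        if self.length_cm < 0 or self.n_snps < 1:
            raise ValueError("chromosome needs length >= 0 cM and >= 1 SNP")


@dataclass
class PanelSpec:
    """Configuration of a simulated mapping panel.

    ``selection`` lists viability-selected loci as tuples
    ``(chrom_label, bp, favored_founder, s)`` with favored_founder in
    {"A", "B"} and selection coefficient s in [0, 1]; each maps to the
    nearest marker on that chromosome.
    """

    n_strains: int
    chromosomes: list
    panel_type: str = "RI"
    n_generations: int = 50
    selection: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 1:
            raise ValueError("need at least one strain/individual")
        self.chromosomes = [
            c if isinstance(c, ChromosomeSpec) else ChromosomeSpec(*c)
            for c in self.chromosomes
        ]
        if self.panel_type not in ("RI", "AIL", "haploid-cross"):
            raise ValueError(f"unknown panel_type {self.panel_type!r}")
        for sel in self.selection:
            if not 0.0 <= float(sel[3]) <= 1.0:
                raise ValueError("selection coefficient must lie in [0, 1]")


@dataclass
class PanelResult:
    """Simulated genotypes plus simulator truth."""

    genotypes: GenotypeMatrix
    theta: AncestryVector
    blocks: pd.DataFrame | None = None
    n_force_fixed_blocks: int = 0
    n_blocks_total: int = 0


def default_panel_spec(n_strains: int = 100, panel_type: str = "RI",
                       seed: int = 0, **kw) -> PanelSpec:
    """Five 80-cM chromosomes with 400 markers each — the default fixture."""
    chroms = [ChromosomeSpec(str(i + 1), 80.0, 400) for i in range(5)]
    return PanelSpec(n_strains=n_strains, chromosomes=chroms,
                     panel_type=panel_type, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Marker maps and meiosis
# ---------------------------------------------------------------------------

def _marker_map(spec: PanelSpec):
    """Per-chromosome marker positions (cM, bp) and adjacent recombination fractions."""
    maps = []
    for c in spec.chromosomes:
        if c.n_snps == 1:
            cm = np.array([0.0])
        else:
            cm = np.linspace(0.0, c.length_cm, c.n_snps)
        bp = (cm * BP_PER_CM).astype(np.int64) + 1
        d = np.diff(cm) / 100.0  # Morgans
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        maps.append((c.label, cm, bp, r))
    return maps


def _gamete(h1, h2, r_adj, rng):
    """One meiotic product of a diploid chromosome under the Haldane map."""
    m = h1.shape[0]
    start = rng.integers(2)
    if m == 1:
        return (h1 if start == 0 else h2).copy()
    switches = rng.random(m - 1) < r_adj
    state = (start + np.concatenate(([0], np.cumsum(switches)))) % 2
    return np.where(state == 0, h1, h2)


def _offspring(mother, father, rmaps, rng):
    return [
        (_gamete(mh[0], mh[1], r, rng), _gamete(fh[0], fh[1], r, rng))
        for (mh, fh, (_, _, _, r)) in zip(mother, father, rmaps)
    ]


def _selection_targets(spec: PanelSpec, rmaps):
    """Resolve selection entries to (chrom_index, marker_index, favored_value, s)."""
    targets = []
    labels = [lab for lab, *_ in rmaps]
    for chrom, bp, founder, s in spec.selection:
        ci = labels.index(str(chrom))
        _, _, bps, _ = rmaps[ci]
        mi = int(np.argmin(np.abs(bps - int(bp))))
        fav = 1 if str(founder).upper() == "A" else 0
        targets.append((ci, mi, fav, float(s)))
    return targets


def _viable(child, targets, rng):
    """Viability check: carriers of a disfavored allele die with probability s."""
    for ci, mi, fav, s in targets:
        h1, h2 = child[ci]
        if h1[mi] != fav or h2[mi] != fav:
            if rng.random() < s:
                return False
    return True


def _draw_offspring(mother, father, rmaps, targets, rng):
    for _ in range(SELECTION_ATTEMPTS):
        child = _offspring(mother, father, rmaps, rng)
        if not targets or _viable(child, targets, rng):
            return child
    raise RuntimeError(
        "no viable offspring within the redraw budget; selection too strong"
    )


def _founder_pair(spec: PanelSpec):
    """The F1 diploid: one chromatid from each founder (A = 1, B = 0)."""
    return [
        (np.ones(c.n_snps, dtype=np.int8), np.zeros(c.n_snps, dtype=np.int8))
        for c in spec.chromosomes
    ]


# ---------------------------------------------------------------------------
# Panel simulators
# ---------------------------------------------------------------------------

def _snp_frame(rmaps):
    rows = []
    for lab, _, bps, _ in rmaps:
        for j, bp in enumerate(bps):
            rows.append((f"c{lab}_s{j}", lab, int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _blocks_from_haplotype(strain, rmaps, haps):
    rows = []
    n_blocks = 0
    for (lab, _, bps, _), h in zip(rmaps, haps):
        change = np.flatnonzero(np.diff(h)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(h)]))
        for s, e in zip(starts, ends):
            rows.append(
                (strain, lab, int(bps[s]), int(bps[e - 1]),
                 "A" if h[s] == 1 else "B", int(e - s))
            )
            n_blocks += 1
    return rows, n_blocks


def simulate_ri_panel(spec: PanelSpec) -> PanelResult:
    """Simulate a recombinant-inbred panel: F2 cross then sib-mating to fixation.

    Each strain is derived independently: an F1 x F1 cross yields a sibling
    pair, which is then sib-mated until all four chromatids agree at every
    marker (or the generation cap is reached, after which each residual
    heterozygous block is fixed by a fair coin flip and the incidence
    logged in ``n_force_fixed_blocks``).
    """
    if spec.panel_type != "RI":
        raise ValueError("spec.panel_type must be 'RI'")
    rng = np.random.default_rng(spec.seed)
    rmaps = _marker_map(spec)
    targets = _selection_targets(spec, rmaps)
    f1 = _founder_pair(spec)

    genotype_rows, block_rows = [], []
    n_forced = 0
    n_blocks_total = 0
    for k in range(spec.n_strains):
        sibs = [
            _draw_offspring(f1, f1, rmaps, targets, rng),
            _draw_offspring(f1, f1, rmaps, targets, rng),
        ]
        fixed_haps = None
        for _ in range(RI_FIXATION_CAP):
            if all(
                np.array_equal(s[c][0], s[c][1])
                and np.array_equal(sibs[0][c][0], sibs[1][c][0])
                for c in range(len(rmaps))
                for s in sibs
            ):
                fixed_haps = [sibs[0][c][0] for c in range(len(rmaps))]
                break
            sibs = [
                _draw_offspring(sibs[0], sibs[1], rmaps, targets, rng),
                _draw_offspring(sibs[0], sibs[1], rmaps, targets, rng),
            ]
        if fixed_haps is None:  # force-fix residual heterozygous blocks
            fixed_haps = []
            for c in range(len(rmaps)):
                h1, h2 = sibs[0][c]
                h = h1.copy()
                het = h1 != h2
                if het.any():
                    edges = np.flatnonzero(np.diff(het.astype(int)))
                    starts = [i + 1 for i in edges if het[i + 1]]
                    if het[0]:
                        starts = [0] + starts
                    for s0 in starts:
                        e0 = s0
                        while e0 < len(het) and het[e0]:
                            e0 += 1
                        if rng.integers(2):
                            h[s0:e0] = h2[s0:e0]
                        n_forced += 1
                fixed_haps.append(h)
        strain = f"RI{k:03d}"
        rows, nb = _blocks_from_haplotype(strain, rmaps, fixed_haps)
        block_rows.extend(rows)
        n_blocks_total += nb
        genotype_rows.append(np.concatenate(fixed_haps).astype(float))

    D = np.vstack(genotype_rows)
    sample_ids = [f"RI{k:03d}" for k in range(spec.n_strains)]
    G = GenotypeMatrix(sample_ids, _snp_frame(rmaps), D)
    theta = AncestryVector(sample_ids, D.mean(axis=1), np.full(len(sample_ids), G.n_snps))
    blocks = pd.DataFrame(
        block_rows, columns=["strain", "chrom", "start_bp", "end_bp", "founder", "n_snps"]
    )
    return PanelResult(G, theta, blocks, n_forced, n_blocks_total)


def simulate_ail(spec: PanelSpec) -> PanelResult:
    """Simulate an advanced intercross line by random mating for n_generations.

    Generation 1 is the F1 (every individual identical and fully
    heterozygous); each later generation pairs a random permutation of the
    population, every pair contributing two offspring.  Emitted dosages are
    {0, 0.5, 1}; theta is the true founder-A fraction over both haplotypes.
    """
    if spec.panel_type != "AIL":
        raise ValueError("spec.panel_type must be 'AIL'")
    n = spec.n_strains
    if n < 20:
        raise ValueError("AIL simulation needs >= 10 breeding pairs (>= 20 individuals)")
    rng = np.random.default_rng(spec.seed)
    rmaps = _marker_map(spec)
    targets = _selection_targets(spec, rmaps)
    pop = [_founder_pair(spec) for _ in range(n)]  # generation 1 = F1

    half = n // 2
    for _ in range(1, spec.n_generations):
        order = rng.permutation(n)
        nxt = []
        for i in range(half):
            mother = pop[order[i]]
            father = pop[order[half + i]]
            nxt.append(_draw_offspring(mother, father, rmaps, targets, rng))
            nxt.append(_draw_offspring(mother, father, rmaps, targets, rng))
        while len(nxt) < n:  # odd population size: one extra offspring
            nxt.append(_draw_offspring(pop[order[0]], pop[order[half]], rmaps, targets, rng))
        pop = nxt[:n]

    sample_ids = [f"AIL{k:04d}" for k in range(n)]
    D = np.vstack([
        np.concatenate([(h1 + h2) / 2.0 for (h1, h2) in ind]) for ind in pop
    ])
    G = GenotypeMatrix(sample_ids, _snp_frame(rmaps), D)
    theta = AncestryVector(sample_ids, D.mean(axis=1), np.full(n, G.n_snps))
    return PanelResult(G, theta)


def simulate_haploid_cross(spec: PanelSpec) -> PanelResult:
    """Haploid progeny from single meioses of the F1 diploid (segregant panel)."""
    if spec.panel_type != "haploid-cross":
        raise ValueError("spec.panel_type must be 'haploid-cross'")
    rng = np.random.default_rng(spec.seed)
    rmaps = _marker_map(spec)
    f1 = _founder_pair(spec)
    sample_ids = [f"SEG{k:04d}" for k in range(spec.n_strains)]
    D = np.vstack([
        np.concatenate([
            _gamete(h1, h2, r, rng) for (h1, h2), (_, _, _, r) in zip(f1, rmaps)
        ]).astype(float)
        for _ in range(spec.n_strains)
    ])
    G = GenotypeMatrix(sample_ids, _snp_frame(rmaps), D)
    theta = AncestryVector(sample_ids, D.mean(axis=1), np.full(spec.n_strains, G.n_snps))
    return PanelResult(G, theta)


def founder_genotypes(spec: PanelSpec) -> GenotypeMatrix:
    """Genotypes of the two founder lines (parent_A = all 1, parent_B = all 0)."""
    rmaps = _marker_map(spec)
    snps = _snp_frame(rmaps)
    D = np.vstack([np.ones(len(snps)), np.zeros(len(snps))])
    return GenotypeMatrix(["parent_A", "parent_B"], snps, D)


def simulate_panel(spec: PanelSpec) -> PanelResult:
    """Dispatch on ``spec.panel_type``."""
    return {
        "RI": simulate_ri_panel,
        "AIL": simulate_ail,
        "haploid-cross": simulate_haploid_cross,
    }[spec.panel_type](spec)
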