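"""Five-taxon synthetic data with configurable ILS and directional HGF.

The generator emulates the data layout the reciprocal ABBA-BABA test
consumes: per-gene five-sequence CDS alignments plus the matching gene
trees, under the species tree (((E_SUB,E_DIP),(C_SUB,C_DIP)),OUT).

Model, per gene (deterministic given (seed, gene_index)):

1.  The ingroup genealogy is the species arrangement, or — with
    probability ``p_ils`` split evenly — one of the two discordant
    arrangements: tetraploids-sister-plus-diploids-sister (K) or the
    reciprocal pairing (F). These two are the symmetric pair under the
    reciprocal quartets (K yields BABA in both test directions, F
    yields ABBA in both), so a pure-ILS data set has E[D] = 0 for both
    D_MAT and D_PAT. ILS is phenomenological (a genealogy class drawn
    per gene), not an explicit coalescent.
2.  Sequences evolve from a uniform random root down the genealogy
    under Jukes-Cantor. Defaults put ~2.6% expected divergence between
    the two diploid lineages and 15% to the outgroup, with the
    subgenomes splitting from their progenitors at a tenth of the
    diploid divergence (a young allopolyploid).
3.  With probability ``f_mat`` / ``f_pat`` / ``f_recip`` the gene
    carries an HGF event modelled as non-crossover conversion: the
    donor's present-day sequence is copied over the recipient
    subgenome (E_SUB -> C_SUB for maternal, C_SUB -> E_SUB for
    paternal, a swap for reciprocal), over the whole gene or a random
    conversion tract (default 200 bp, the expected scale of
    homoeologous gene conversion). Residual post-conversion divergence
    of polyploid_age_fraction x diploid_divergence / 2 is then applied
    to each overwritten segment.

The emitted gene tree reflects the realized history in whole-gene mode
(HGF events produce the corresponding overwriting topology); in tract
mode it carries the whole-gene majority genealogy while the truth
record carries tract coordinates (0-based, half-open).

The generator draws genealogy class and HGF event before any sequence
randomness, so raising an HGF rate at a fixed seed converts a superset
of the genes converted at a lower rate — D responds monotonically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import __version__
from .io_model import GeneAlignment, GeneTree, IngroupNode, RoleMap, ROLES, write_gene_alignment

_SPECIES_TOP: IngroupNode = (("E_SUB", "E_DIP"), ("C_SUB", "C_DIP"))
_ILS_K: IngroupNode = (("E_SUB", "C_SUB"), ("E_DIP", "C_DIP"))
_ILS_F: IngroupNode = (("E_SUB", "C_DIP"), ("C_SUB", "E_DIP"))
_TOP_L: IngroupNode = ((("E_SUB", "C_SUB"), "E_DIP"), "C_DIP")  # E overwrites C
_TOP_M: IngroupNode = ((("E_SUB", "C_SUB"), "C_DIP"), "E_DIP")  # C overwrites E

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; defaults are the study conditions being emulated.

    Rates are per-gene probabilities; divergences are expected
    substitutions per site (Jukes-Cantor branch lengths).
    """

    n_genes: int = 1000
    gene_length: int = 300
    diploid_divergence: float = 0.026
    outgroup_divergence: float = 0.15
    polyploid_age_fraction: float = 0.1
    p_ils: float = 0.05
    f_mat: float = 0.0
    f_pat: float = 0.0
    f_recip: float = 0.0
    tract_mode: str = "whole_gene"
    tract_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length < 3 or self.gene_length % 3:
            raise ValueError("gene_length must be a positive multiple of 3")
        for name in ("diploid_divergence", "outgroup_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.polyploid_age_fraction <= 1:
            raise ValueError("polyploid_age_fraction must be in [0, 1]")
        rates = (self.f_mat, self.f_pat, self.f_recip)
        if any(r < 0 for r in rates) or sum(rates) > 1:
            raise ValueError("f_mat + f_pat + f_recip must be in [0, 1]")
        if not 0 <= self.p_ils <= 1:
            raise ValueError("p_ils must be in [0, 1]")
        if self.tract_mode not in ("whole_gene", "tract"):
            raise ValueError("tract_mode must be 'whole_gene' or 'tract'")
        if self.tract_length < 1:
            raise ValueError("tract_length must be >= 1")
        if self.outgroup_divergence < self.diploid_divergence:
            raise ValueError("outgroup_divergence must be >= diploid_divergence")


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    genealogy: str            # species | ils_tetra_sister | ils_reciprocal
    hgf_event: Optional[str]  # mat | pat | recip | None
    tract_start: Optional[int] = None  # 0-based, half-open
    tract_end: Optional[int] = None


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch: expected t substitutions/site."""
    out = seq.copy()
    if t <= 0:
        return out
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    mask = rng.random(out.size) < p
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return out


def _heights(params: SimulationParams) -> Tuple[float, float, float, float]:
    """(root, discordant ingroup root, ingroup crown, polyploid split)."""
    h_crown = params.diploid_divergence / 2.0
    h_root = params.outgroup_divergence / 2.0
    h_split = params.polyploid_age_fraction * h_crown
    # Discordant coalescences happen deeper than the species crown;
    # place the discordant root midway between crown and tree root.
    h_disc = h_crown + 0.5 * (h_root - h_crown)
    return h_root, h_disc, h_crown, h_split


def simulate_gene(
    params: SimulationParams, gene_index: int
) -> Tuple[GeneAlignment, GeneTree, GeneTruth]:
    """Simulate one gene; deterministic given (params.seed, gene_index)."""
    rng = np.random.default_rng([params.seed, gene_index])
    L = params.gene_length
    h_root, h_disc, h_crown, h_split = _heights(params)

    # -- draws that define the gene's history (fixed order, see module doc)
    u_gen = rng.random()
    u_hgf = rng.random()
    if u_gen < params.p_ils / 2.0:
        genealogy = "ils_tetra_sister"
    elif u_gen < params.p_ils:
        genealogy = "ils_reciprocal"
    else:
        genealogy = "species"
    if u_hgf < params.f_mat:
        event: Optional[str] = "mat"
    elif u_hgf < params.f_mat + params.f_pat:
        event = "pat"
    elif u_hgf < params.f_mat + params.f_pat + params.f_recip:
        event = "recip"
    else:
        event = None

    # -- sequence evolution down the drawn genealogy
    root = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs: Dict[str, np.ndarray] = {"OUT": _evolve(root, h_root, rng)}
    if genealogy == "species":
        crown = _evolve(root, h_root - h_crown, rng)
        e_anc = _evolve(crown, h_crown - h_split, rng)
        c_anc = _evolve(crown, h_crown - h_split, rng)
        seqs["E_SUB"] = _evolve(e_anc, h_split, rng)
        seqs["E_DIP"] = _evolve(e_anc, h_split, rng)
        seqs["C_SUB"] = _evolve(c_anc, h_split, rng)
        seqs["C_DIP"] = _evolve(c_anc, h_split, rng)
        topo = _SPECIES_TOP
    else:
        pairs = (
            (("E_SUB", "C_SUB"), ("E_DIP", "C_DIP"))
            if genealogy == "ils_tetra_sister"
            else (("E_SUB", "C_DIP"), ("C_SUB", "E_DIP"))
        )
        disc_root = _evolve(root, h_root - h_disc, rng)
        for pair in pairs:
            anc = _evolve(disc_root, h_disc - h_crown, rng)
            for leaf in pair:
                seqs[leaf] = _evolve(anc, h_crown, rng)
        topo = _ILS_K if genealogy == "ils_tetra_sister" else _ILS_F

    # -- homoeologous conversion (copy donor -> recipient, plus residual)
    tract_start = tract_end = None
    if event is not None:
        if params.tract_mode == "tract":
            t_len = min(params.tract_length, L)
            tract_start = int(rng.integers(0, L - t_len + 1))
            tract_end = tract_start + t_len
        else:
            tract_start, tract_end = 0, L
        sl = slice(tract_start, tract_end)
        residual = params.polyploid_age_fraction * params.diploid_divergence / 2.0
        if event == "mat":
            seqs["C_SUB"][sl] = _evolve(seqs["E_SUB"][sl], residual, rng)
        elif event == "pat":
            seqs["E_SUB"][sl] = _evolve(seqs["C_SUB"][sl], residual, rng)
        else:
            e_tract = seqs["E_SUB"][sl].copy()
            seqs["E_SUB"][sl] = _evolve(seqs["C_SUB"][sl], residual, rng)
            seqs["C_SUB"][sl] = _evolve(e_tract, residual, rng)
        if params.tract_mode == "whole_gene":
            topo = {"mat": _TOP_L, "pat": _TOP_M, "recip": _ILS_F}[event]
        # tract mode: emitted tree keeps the whole-gene majority genealogy

    gene_id = f"gene{gene_index:05d}"
    alignment = GeneAlignment(
        gene_id=gene_id,
        sequences={
            role: _BASES[seqs[role]].tobytes().decode("ascii") for role in ROLES
        },
    )
    tree = GeneTree(gene_id=gene_id, ingroup=topo, supports=(100.0, 100.0))
    truth = GeneTruth(
        gene_id=gene_id,
        genealogy=genealogy,
        hgf_event=event,
        tract_start=tract_start,
        tract_end=tract_end,
    )
    return alignment, tree, truth


def simulate_dataset(
    params: SimulationParams, out_dir: Optional[Union[str, Path]] = None
) -> Tuple[List[GeneAlignment], List[GeneTree], List[GeneTruth], Dict]:
    """Simulate ``n_genes`` independent genes; optionally write to disk.

    When ``out_dir`` is given, writes per-gene FASTA under
    ``alignments/``, per-gene newick under ``trees/``, a ``truth.tsv``,
    a role-map TSV matching the emitted headers, and a JSON manifest
    recording all parameters.
    """
    alignments: List[GeneAlignment] = []
    trees: List[GeneTree] = []
    truths: List[GeneTruth] = []
    for i in range(params.n_genes):
        a, t, tr = simulate_gene(params, i)
        alignments.append(a)
        trees.append(t)
        truths.append(tr)
    manifest = {
        "generator": f"hgflow {__version__}",
        "params": dataclasses.asdict(params),
        "seed": params.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        (out / "trees").mkdir(parents=True, exist_ok=True)
        for a, t in zip(alignments, trees):
            write_gene_alignment(a, out / "alignments" / f"{a.gene_id}.fasta")
            (out / "trees" / f"{t.gene_id}.nwk").write_text(
                _supported_newick(t) + "\n"
            )
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene_id\tgenealogy\thgf_event\ttract_start\ttract_end\n")
            for tr in truths:
                fh.write(
                    f"{tr.gene_id}\t{tr.genealogy}\t{tr.hgf_event or 'none'}\t"
                    f"{'' if tr.tract_start is None else tr.tract_start}\t"
                    f"{'' if tr.tract_end is None else tr.tract_end}\n"
                )
        with open(out / "rolemap.tsv", "w") as fh:
            for role in ROLES:
                fh.write(f"{role}\t^{role}$\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return alignments, trees, truths, manifest


def _supported_newick(tree: GeneTree) -> str:
    """Newick with bootstrap labels on internal ingroup nodes."""
    supports = [s for s in tree.supports if s is not None]

    def render(node: IngroupNode, is_root: bool) -> str:
        if isinstance(node, str):
            return node
        inner = ",".join(render(c, False) for c in node)
        if is_root:
            return f"({inner})"
        sup = supports[0] if supports else 100.0
        return f"({inner}){sup:g}"

    return f"({render(tree.ingroup, True)},OUT);"


def default_rolemap() -> RoleMap:
    """Role map matching the simulator's FASTA headers / leaf labels."""
    return RoleMap.exact()
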