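"""Structure-guided comparative mutant design.

Given a pairwise alignment of a thermophilic enzyme (sequence A) with a
mesophilic homologue (sequence B) and a ligand-bound structure of A, this
module implements the three design rules used to build candidate mutants:

1. substitutions that are structurally close to each other are grouped into
   the same mutant construct (single-linkage clustering on minimum
   heavy-atom distance, default link threshold 6 A);
2. only residues within a distance shell (8 or 12 A) of any atom of the
   bound substrate or coenzyme are candidates, where distances are minima
   over heavy atoms, over all ligand copies, over all chains (cross-subunit
   proximity counts);
3. residues inserted in B are carried into a construct when an immediately
   flanking aligned column is one of the construct's substitutions.
"""
from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentColumn", "PairwiseAlignmentMap", "AlignmentSummary",
    "ResidueDistanceMap", "CandidateSite", "MutantDesign",
    "align_global", "read_aligned_fasta", "summarize_alignment",
    "parse_structure", "compute_distance_map", "select_shell_sites",
    "group_sites", "apply_insertion_rule", "combine_designs",
    "candidates_to_tsv", "designs_to_json",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignmentColumn:
    a: str | None  # residue in sequence A, None for a gap
    b: str | None
    pos_a: int | None  # 1-based ungapped position in A
    pos_b: int | None


@dataclass
class PairwiseAlignmentMap:
    name_a: str
    name_b: str
    columns: list[AlignmentColumn]

    def validate(self) -> None:
        last_a = last_b = 0
        for col in self.columns:
            if col.a is None and col.b is None:
                raise ValueError("column gapped in both sequences")
            if col.pos_a is not None:
                if col.pos_a <= last_a:
                    raise ValueError("positions in A not strictly increasing")
                last_a = col.pos_a
            if col.pos_b is not None:
                if col.pos_b <= last_b:
                    raise ValueError("positions in B not strictly increasing")
                last_b = col.pos_b


@dataclass(frozen=True)
class AlignmentSummary:
    aligned_length: int  # columns with residues in both sequences
    identical: int
    different: int
    insertions_in_B: int  # residues of B falling in gaps of A


def _columns_from_strings(name_a, name_b, row_a: str, row_b: str) -> PairwiseAlignmentMap:
    cols, pa, pb = [], 0, 0
    for ca, cb in zip(row_a, row_b):
        a = None if ca == "-" else ca
        b = None if cb == "-" else cb
        if a is not None:
            pa += 1
        if b is not None:
            pb += 1
        cols.append(AlignmentColumn(a, b, pa if a else None, pb if b else None))
    aln = PairwiseAlignmentMap(name_a, name_b, cols)
    aln.validate()
    return aln


def align_global(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 name_a: str = "A", name_b: str = "B") -> PairwiseAlignmentMap:
    """Optimal global pairwise alignment (Needleman-Wunsch).

    Tie-breaking among co-optimal alignments is deterministic: the first
    alignment enumerated by the dynamic-programming traceback is used.
    """
    for name, seq in [(name_a, seq_a), (name_b, seq_b)]:
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - VALID_AA
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid characters: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    best = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(best[0]), str(best[1])
    return _columns_from_strings(name_a, name_b, row_a, row_b)


def read_aligned_fasta(path_or_handle) -> PairwiseAlignmentMap:
    """Two-record aligned FASTA (equal lengths, '-' gaps) -> alignment map."""
    if isinstance(path_or_handle, str) and "\n" in path_or_handle:
        path_or_handle = io.StringIO(path_or_handle)
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 records, got {len(records)}")
    a, b = records
    if len(a.seq) != len(b.seq):
        raise ValueError("aligned records must have equal lengths")
    return _columns_from_strings(a.id, b.id, str(a.seq).upper(), str(b.seq).upper())


def summarize_alignment(aln: PairwiseAlignmentMap) -> AlignmentSummary:
    aln.validate()
    identical = different = insertions = 0
    for col in aln.columns:
        if col.a is not None and col.b is not None:
            if col.a == col.b:
                identical += 1
            else:
                different += 1
        elif col.a is None:
            insertions += 1
    return AlignmentSummary(aligned_length=identical + different,
                            identical=identical, different=different,
                            insertions_in_B=insertions)


# ---------------------------------------------------------------------------
# Structure distances


@dataclass
class ResidueDistanceMap:
    """Per-residue minimum heavy-atom distance to each bound ligand.

    Keys are (chain, residue number, residue name); distances are minima
    over all heavy atoms of the residue and all heavy atoms of every copy of
    the ligand in any chain.
    """

    ligand_names: list[str]
    entries: dict[tuple[str, int, str], dict[str, float]] = field(default_factory=dict)

    def min_distance(self, chain: str, resnum: int) -> float | None:
        """Distance to the nearest ligand of any kind; min over matching keys."""
        best = None
        for (ch, num, _), dists in self.entries.items():
            if ch == chain and num == resnum:
                d = min(dists.values())
                best = d if best is None else min(best, d)
        return best

    def min_distance_any_chain(self, resnum: int) -> float | None:
        ds = [min(d.values()) for (ch, num, _), d in self.entries.items()
              if num == resnum]
        return min(ds) if ds else None


def parse_structure(pdb_text_or_path: str) -> gemmi.Structure:
    if "\n" in pdb_text_or_path:
        st = gemmi.read_pdb_string(pdb_text_or_path)
    else:
        st = gemmi.read_structure(pdb_text_or_path)
    st.setup_entities()
    return st


def _heavy_atom_coords(residue: gemmi.Residue) -> np.ndarray:
    pos = [[a.pos.x, a.pos.y, a.pos.z] for a in residue
           if not a.is_hydrogen()]
    return np.asarray(pos, dtype=float)


def compute_distance_map(structure: gemmi.Structure,
                         ligand_names: list[str] = ("IPM", "NAD"),
                         ) -> ResidueDistanceMap:
    """Minimum heavy-atom distance from every polymer residue to each ligand."""
    model = structure[0]
    ligand_names = list(ligand_names)
    lig_coords: dict[str, list[np.ndarray]] = {n: [] for n in ligand_names}
    polymer: list[tuple[tuple[str, int, str], np.ndarray]] = []
    available_het = set()
    for chain in model:
        for res in chain:
            coords = _heavy_atom_coords(res)
            if coords.size == 0:
                continue
            if res.name in lig_coords:
                lig_coords[res.name].append(coords)
            elif res.het_flag == "H" and res.name != "HOH":
                available_het.add(res.name)
            elif res.het_flag != "H":
                polymer.append(((chain.name, res.seqid.num, res.name), coords))
    missing = [n for n, c in lig_coords.items() if not c]
    if missing:
        raise ValueError(
            f"ligand(s) {missing} not found in structure; available HET "
            f"groups: {sorted(available_het) or 'none'}")
    lig_stacked = {n: np.vstack(c) for n, c in lig_coords.items()}
    dmap = ResidueDistanceMap(ligand_names=ligand_names)
    for key, coords in polymer:
        dists = {}
        for name, lcoords in lig_stacked.items():
            diff = coords[:, None, :] - lcoords[None, :, :]
            dists[name] = float(np.sqrt((diff ** 2).sum(axis=2)).min())
        dmap.entries[key] = dists
    return dmap


# ---------------------------------------------------------------------------
# Site selection, grouping, insertion rule


@dataclass(frozen=True)
class CandidateSite:
    position_a: int  # 1-based position in sequence A
    from_aa: str
    to_aa: str
    resnum: int  # structure residue number (position_a + offset)
    min_distance: float  # A, to the nearest ligand
    column_index: int  # index into the alignment columns


@dataclass
class MutantDesign:
    name: str
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    insertions: list[tuple[int, str]] = field(default_factory=list)
    shell: float | None = None

    def validate(self, seq_a: str | None = None) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValueError("substitution positions must be unique")
        if seq_a is not None:
            for pos, frm, _ in self.substitutions:
                if seq_a[pos - 1] != frm:
                    raise ValueError(
                        f"from-residue {frm} does not match sequence A at {pos}")

    def mutation_strings(self) -> list[str]:
        return [f"{frm}{pos}{to}" for pos, frm, to in
                sorted(self.substitutions)]


def select_shell_sites(aln: PairwiseAlignmentMap, dmap: ResidueDistanceMap,
                       radius: float, offset: int = 0) -> list[CandidateSite]:
    """Differing aligned residues within ``radius`` of any bound ligand.

    Sequence-A position p maps to structure residue number p + offset;
    distances are minima over all chains carrying that residue number.
    Positions absent from the structure are skipped with a warning.
    """
    out = []
    for i, col in enumerate(aln.columns):
        if col.a is None or col.b is None or col.a == col.b:
            continue
        resnum = col.pos_a + offset
        d = dmap.min_distance_any_chain(resnum)
        if d is None:
            warnings.warn(f"alignment position {col.pos_a} (residue {resnum}) "
                          "absent from structure; skipped", stacklevel=2)
            continue
        if d <= radius:
            out.append(CandidateSite(position_a=col.pos_a, from_aa=col.a,
                                     to_aa=col.b, resnum=resnum,
                                     min_distance=d, column_index=i))
    return out


def _residue_coords_by_number(structure: gemmi.Structure) -> dict[int, np.ndarray]:
    coords: dict[int, list[np.ndarray]] = {}
    for chain in structure[0]:
        for res in chain:
            if res.het_flag == "H":
                continue
            c = _heavy_atom_coords(res)
            if c.size:
                coords.setdefault(res.seqid.num, []).append(c)
    return {num: np.vstack(cs) for num, cs in coords.items()}


def group_sites(candidates: list[CandidateSite], structure: gemmi.Structure,
                link_threshold: float = 6.0, shell: float | None = None,
                name_prefix: str = "mut#") -> list[MutantDesign]:
    """Single-linkage clustering of candidate sites into mutant constructs.

    Sites whose minimum inter-residue heavy-atom distance is at or below the
    link threshold end up in the same construct. Constructs are numbered by
    their lowest residue number.
    """
    if not candidates:
        return []
    coords = _residue_coords_by_number(structure)
    n = len(candidates)
    rows, cols = [], []
    for i in range(n):
        ci = coords[candidates[i].resnum]
        for j in range(i + 1, n):
            cj = coords[candidates[j].resnum]
            diff = ci[:, None, :] - cj[None, :, :]
            d = float(np.sqrt((diff ** 2).sum(axis=2)).min())
            if d <= link_threshold:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters: dict[int, list[CandidateSite]] = {}
    for site, lab in zip(candidates, labels):
        clusters.setdefault(int(lab), []).append(site)
    ordered = sorted(clusters.values(), key=lambda c: min(s.resnum for s in c))
    designs = []
    for k, cluster in enumerate(ordered, start=1):
        subs = sorted((s.position_a, s.from_aa, s.to_aa) for s in cluster)
        designs.append(MutantDesign(name=f"{name_prefix}{k}",
                                    substitutions=subs, shell=shell))
    return designs


def apply_insertion_rule(designs: list[MutantDesign],
                         aln: PairwiseAlignmentMap) -> list[MutantDesign]:
    """Attach B-insertions whose flanking aligned column is substituted.

    Insertion runs (consecutive columns gapped in A) are attached to every
    design containing a substitution at the immediately flanking aligned
    column on either side; attachment to more than one design is logged.
    """
    cols = aln.columns
    # collect insertion runs: (start, end) inclusive column indices
    runs = []
    i = 0
    while i < len(cols):
        if cols[i].a is None:
            j = i
            while j + 1 < len(cols) and cols[j + 1].a is None:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    sub_positions = [{p for p, _, _ in d.substitutions} for d in designs]
    out = [replace(d, substitutions=list(d.substitutions),
                   insertions=list(d.insertions)) for d in designs]
    for start, end in runs:
        inserted = "".join(cols[k].b for k in range(start, end + 1))
        left = cols[start - 1] if start > 0 else None
        right = cols[end + 1] if end + 1 < len(cols) else None
        flank_positions = set()
        for flank in (left, right):
            if flank is not None and flank.a is not None and flank.b is not None \
                    and flank.a != flank.b:
                flank_positions.add(flank.pos_a)
        after = left.pos_a if left is not None and left.pos_a is not None else 0
        hits = [k for k, subs in enumerate(sub_positions)
                if subs & flank_positions]
        if len(hits) > 1:
            logger.warning("insertion %r after position %d flanked by "
                           "substitutions in %d designs; attached to all",
                           inserted, after, len(hits))
        for k in hits:
            out[k].insertions.append((after, inserted))
    return out


def combine_designs(a: MutantDesign, b: MutantDesign) -> MutantDesign:
    """Union of two constructs' substitutions and insertions.

    Conflicting target residues at the same position are an error; the name
    concatenates the numeric parts ("mut#9" + "mut#21" -> "mut9/21").
    """
    subs = {p: (frm, to) for p, frm, to in a.substitutions}
    for p, frm, to in b.substitutions:
        if p in subs and subs[p] != (frm, to):
            raise ValueError(f"conflicting substitutions at position {p}: "
                             f"{subs[p]} vs {(frm, to)}")
        subs[p] = (frm, to)
    insertions = list(dict.fromkeys(list(a.insertions) + list(b.insertions)))
    if a.name == b.name and a.substitutions == b.substitutions:
        name = a.name
    else:
        name = f"{a.name.replace('#', '')}/{b.name.replace('#', '').removeprefix('mut')}"
    return MutantDesign(
        name=name,
        substitutions=sorted((p, fr, to) for p, (fr, to) in subs.items()),
        insertions=insertions,
        shell=max(filter(None, [a.shell, b.shell]), default=None))


def candidates_to_tsv(candidates: list[CandidateSite],
                      dmap: ResidueDistanceMap, radius: float) -> str:
    lines = ["position\tfromAA\ttoAA\t"
             + "\t".join(f"d_{n}_A" for n in dmap.ligand_names)
             + "\twithin_shell"]
    by_num = {}
    for (ch, num, _), dists in dmap.entries.items():
        cur = by_num.setdefault(num, dict.fromkeys(dmap.ligand_names, np.inf))
        for n, d in dists.items():
            cur[n] = min(cur[n], d)
    for c in candidates:
        dists = by_num[c.resnum]
        lines.append(f"{c.position_a}\t{c.from_aa}\t{c.to_aa}\t"
                     + "\t".join(f"{dists[n]:.2f}" for n in dmap.ligand_names)
                     + f"\t{c.min_distance <= radius}")
    return "\n".join(lines) + "\n"


def designs_to_json(designs: list[MutantDesign]) -> str:
    return json.dumps([{
        "name": d.name,
        "substitutions": d.mutation_strings(),
        "insertions": [{"after_position": p, "residues": r}
                       for p, r in d.insertions],
        "shell_A": d.shell,
    } for d in designs], indent=2)
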