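"""Core data model and readers for trees, alignments, structures and assay tables.

All public APIs speak reference site labels (1-based positions in a chosen
reference sequence, the field's "sheep numbering" convention for ATP1A);
internal column indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from Bio import SeqIO
from Bio.PDB import PDBParser

GAP = "-"
MISSING = "X"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: IUPAC ambiguity codes expand to uniform partial likelihoods over these sets
AMBIGUITY = {
    "B": "ND",
    "Z": "QE",
    "J": "IL",
    "X": AMINO_ACIDS,
    "?": AMINO_ACIDS,
}


class Phylogeny:
    """Rooted tree with branch lengths in expected substitutions/site.

    Nodes are integer ids; every non-root node carries the length of the
    branch above it, so a branch is identified by its child node id.
    Polytomies are allowed.
    """

    def __init__(self, parent, branch_length, labels, root):
        self.parent: dict[int, int] = dict(parent)
        self.branch_length: dict[int, float] = dict(branch_length)
        self.labels: dict[int, str] = dict(labels)
        self.root: int = root
        self.children: dict[int, list[int]] = {n: [] for n in self.nodes()}
        for c, p in self.parent.items():
            self.children[p].append(c)
        self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, default_length=None) -> "Phylogeny":
        parent, blen, labels = {}, {}, {}
        ids = {}
        for i, nd in enumerate(dtree.preorder_node_iter()):
            ids[nd] = i
            if nd.parent_node is not None:
                parent[i] = ids[nd.parent_node]
                if nd.edge.length is None:
                    if default_length is None:
                        raise ValueError(f"missing branch length above node {i}")
                    warnings.warn("missing branch length set to default")
                    blen[i] = float(default_length)
                else:
                    blen[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        root = ids[dtree.seed_node]
        return cls(parent, blen, labels, root)

    @classmethod
    def read_newick(cls, path, default_length=None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                      preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader\
                .NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"tip labels are not unique: {err}") from err
        return cls.from_dendropy(dtree, default_length=default_length)

    @classmethod
    def from_newick_string(cls, s: str, default_length=None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(data=s, schema="newick",
                                      preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader\
                .NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"tip labels are not unique: {err}") from err
        return cls.from_dendropy(dtree, default_length=default_length)

    def _validate(self):
        tips = [self.labels.get(n) for n in self.tips()]
        if any(t is None for t in tips):
            raise ValueError("unlabeled tip")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels are not unique")
        if any(l < 0 for l in self.branch_length.values()):
            raise ValueError("negative branch length")
        # connectivity/acyclicity: every non-root node must reach the root
        for n in self.nodes():
            seen, cur = set(), n
            while cur != self.root:
                if cur in seen:
                    raise ValueError("cycle in parent map")
                seen.add(cur)
                cur = self.parent[cur]

    # -- traversal ----------------------------------------------------
    def nodes(self):
        ns = set(self.parent) | {self.root} | set(self.parent.values())
        return sorted(ns)

    def tips(self):
        par_set = set(self.parent.values()) | {self.root}
        return [n for n in self.nodes() if n not in par_set]

    def internal_nodes(self):
        tipset = set(self.tips())
        return [n for n in self.nodes() if n not in tipset]

    def is_tip(self, n):
        return not self.children[n]

    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    def tip_for_label(self, label):
        for n in self.tips():
            if self.labels.get(n) == label:
                return n
        raise KeyError(label)

    # -- geometry -----------------------------------------------------
    def ancestors(self, n):
        out = []
        while n != self.root:
            n = self.parent[n]
            out.append(n)
        return out

    def is_ancestor(self, a, b):
        """True if node a lies on the path from b to the root (a != b)."""
        return a in self.ancestors(b)

    def mrca(self, a, b):
        anc_a = [a] + self.ancestors(a)
        on_path = set(anc_a)
        cur = b
        while cur not in on_path:
            cur = self.parent[cur]
        return cur

    def depth(self, n):
        """Sum of branch lengths from the root down to node n."""
        d = 0.0
        while n != self.root:
            d += self.branch_length[n]
            n = self.parent[n]
        return d

    def patristic(self, a, b):
        m = self.mrca(a, b)
        return self.depth(a) + self.depth(b) - 2 * self.depth(m)

    # -- output -------------------------------------------------------
    def _newick_node(self, n, fmt):
        if self.is_tip(n):
            s = self.labels[n]
        else:
            s = "(" + ",".join(self._newick_node(c, fmt) for c in self.children[n]) + ")"
            if n in self.labels:
                s += self.labels[n]
        if n != self.root:
            s += ":" + fmt % self.branch_length[n]
        return s

    def to_newick(self, precision=10) -> str:
        return self._newick_node(self.root, f"%.{precision}g") + ";"

    def write_newick(self, path, precision=10):
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision=precision) + "\n")

    def copy(self):
        return Phylogeny(self.parent, self.branch_length, self.labels, self.root)


def read_tree(path, default_length=None) -> Phylogeny:
    """Read a Newick tree; missing branch lengths raise unless a default is given."""
    return Phylogeny.read_newick(path, default_length=default_length)


@dataclass
class Alignment:
    """Amino-acid alignment with a reference-coordinate numbering map.

    ``column_labels[j]`` is the reference site label of column j, or None for
    columns where the reference has a gap (insertion columns).
    """

    ids: list[str]
    matrix: np.ndarray  # shape (n_seq, n_col), dtype '<U1'
    column_labels: list[int | None] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if not self.column_labels:
            self.column_labels = list(range(1, self.matrix.shape[1] + 1))
        self._site_to_col = {}
        for j, lab in enumerate(self.column_labels):
            if lab is None:
                continue
            if lab in self._site_to_col:
                raise ValueError(f"site label {lab} maps to more than one column")
            self._site_to_col[lab] = j

    @property
    def n_seq(self):
        return self.matrix.shape[0]

    @property
    def n_col(self):
        return self.matrix.shape[1]

    def row(self, seq_id) -> np.ndarray:
        return self.matrix[self.ids.index(seq_id)]

    def column_of_site(self, site: int) -> int:
        return self._site_to_col[site]

    def site_of_column(self, col: int):
        return self.column_labels[col]

    def column(self, site: int) -> np.ndarray:
        return self.matrix[:, self.column_of_site(site)]

    def sites(self):
        return [l for l in self.column_labels if l is not None]

    def gap_only_columns(self):
        return [j for j in range(self.n_col)
                if np.all(self.matrix[:, j] == GAP)]

    def write_fasta(self, path):
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{''.join(self.matrix[i])}\n")


def read_alignment(path, reference_id=None, offset=0) -> Alignment:
    """Read a FASTA alignment and number columns by ungapped position in
    ``reference_id`` (plus ``offset``); default numbering is 1..L.

    Columns where the reference carries a gap are insertion columns and get
    label None.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    if reference_id is None:
        labels = list(range(1 + offset, matrix.shape[1] + 1 + offset))
    else:
        if reference_id not in ids:
            raise ValueError(f"reference {reference_id!r} not in alignment")
        ref = matrix[ids.index(reference_id)]
        labels, pos = [], 0
        for c in ref:
            if c == GAP:
                labels.append(None)
            else:
                pos += 1
                labels.append(pos + offset)
    return Alignment(ids=ids, matrix=matrix, column_labels=labels)


@dataclass
class StructureModel:
    """Alpha-carbon coordinates (Å) for one chain of a crystal structure."""

    chain: str
    coords: dict[int, np.ndarray]  # residue number -> (3,) array

    def distance(self, res_a: int, res_b: int) -> float:
        return float(np.linalg.norm(self.coords[res_a] - self.coords[res_b]))


def read_structure(path, chain: str) -> StructureModel:
    """Extract CA coordinates for one chain from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not present")
    coords = {}
    for residue in model[chain]:
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy())
        coords[residue.id[1]] = np.asarray(atom.get_coord(), dtype=float)
    return StructureModel(chain=chain, coords=coords)


# Concentrations used in the ouabain inhibition series, molar, decreasing.
OUABAIN_CONCENTRATIONS = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)

ASSAY_COLUMNS = ["construct", "background", "substitution", "replicate",
                 "conc_M", "absorbance", "well_type"]


@dataclass
class AssayRecord:
    """One biological replicate of one construct on the ouabain plate.

    ``dose_absorbance`` maps molar ouabain concentration to (technical-
    replicate-averaged) absorbance; ``control`` is the no-ouabain well and
    ``background`` the fully inhibited well.
    """

    construct: str
    background_id: str
    substitution: tuple[str, int, str] | None  # (from, site, to) or None for wt
    replicate: int
    dose_absorbance: dict[float, float]
    control_absorbance: float
    background_absorbance: float
    protein_mass_mg: float = 0.1
    incubation_min: float = 20.0

    def __post_init__(self):
        concs = list(self.dose_absorbance)
        if any(b - a <= 0 for a, b in zip(concs[1:], concs[:-1])):
            raise ValueError("concentrations must be strictly decreasing")
        if any(v < 0 for v in self.dose_absorbance.values()):
            raise ValueError("negative absorbance")


def read_assay_table(path) -> list[AssayRecord]:
    """Read the long-format assay CSV (one row per well) into AssayRecords.

    Expected header: construct,background,substitution,replicate,conc_M,
    absorbance,well_type with well_type in {dose, control, background}.
    Duplicate wells (technical replicates) are averaged.
    """
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    records = []
    for (construct, bg, sub, rep), grp in df.groupby(
            ["construct", "background", "substitution", "replicate"],
            dropna=False, sort=False):
        doses = (grp[grp.well_type == "dose"]
                 .groupby("conc_M").absorbance.mean()
                 .sort_index(ascending=False))
        control = grp[grp.well_type == "control"].absorbance.mean()
        backgrd = grp[grp.well_type == "background"].absorbance.mean()
        parsed = None
        if isinstance(sub, str) and sub and sub.lower() != "wt":
            parsed = (sub[0], int(sub[1:-1]), sub[-1])
        records.append(AssayRecord(
            construct=str(construct), background_id=str(bg),
            substitution=parsed, replicate=int(rep),
            dose_absorbance=dict(doses), control_absorbance=float(control),
            background_absorbance=float(backgrd)))
    return records


def write_assay_table(records, path):
    rows = []
    for r in records:
        sub = "" if r.substitution is None else \
            f"{r.substitution[0]}{r.substitution[1]}{r.substitution[2]}"
        for conc, ab in r.dose_absorbance.items():
            rows.append((r.construct, r.background_id, sub, r.replicate,
                         conc, ab, "dose"))
        rows.append((r.construct, r.background_id, sub, r.replicate,
                     np.nan, r.control_absorbance, "control"))
        rows.append((r.construct, r.background_id, sub, r.replicate,
                     np.nan, r.background_absorbance, "background"))
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, index=False)
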