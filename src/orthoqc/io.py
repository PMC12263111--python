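"""Readers and writers for the standard formats the pipeline touches.

All readers normalize into the :mod:`orthoqc.model` containers; GFF3
coordinates are converted from 1-based inclusive on disk to the internal
0-based half-open convention, and back on writing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree

from .model import (
    AnnotationSet,
    DataError,
    FormatError,
    GeneModel,
    GenomicInterval,
    HOG,
    HOGCollection,
    OrthologPairs,
    Proteome,
    ProteinRecord,
    SpeciesTree,
    SpliceMap,
    TranscriptModel,
    TreeNode,
)

PathLike = Union[str, Path]

ORTHOXML_NS = "http://orthoXML.org/2011/"


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

#: default pattern extracting the parent gene id from a FASTA description
DEFAULT_GENE_PATTERN = r"gene[:=](\S+)"


def parse_fasta(path: PathLike, species: str = "", label: str = "",
                gene_pattern: str = DEFAULT_GENE_PATTERN) -> Proteome:
    """Read a protein FASTA into a :class:`Proteome`.

    The parent gene id is extracted from the record description with
    ``gene_pattern`` (first group); records without a match are treated as
    single-protein genes (gene id = protein id). Canonical flags start
    false; see :func:`orthoqc.orthology.select_canonical_longest`.
    """
    path = Path(path)
    species = species or path.stem
    label = label or path.stem
    pat = re.compile(gene_pattern)
    proteome = Proteome(label=label, species=species)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        m = pat.search(rec.description)
        gene_id = m.group(1) if m else rec.id
        if rec.id in proteome:
            raise FormatError(f"{path}: duplicate header {rec.id!r}")
        proteome.add(ProteinRecord(id=rec.id, gene_id=gene_id, species=species,
                                   sequence=seq))
    return proteome


def write_fasta(proteome: Proteome, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"gene={p.gene_id}")
        for p in sorted(proteome, key=lambda p: p.id)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Gff3Dialect:
    """Reader configuration for one GFF3 flavour.

    ``biotype_keys`` lists the attribute keys that may carry the gene
    biotype; a gene is kept iff no such key is present (assumed coding, as
    for purely protein-coding predictors) or its value is in
    ``coding_values``.
    """

    name: str
    biotype_keys: Tuple[str, ...] = ("biotype", "gene_biotype")
    coding_values: Tuple[str, ...] = ("protein_coding",)
    transcript_types: Tuple[str, ...] = ("mRNA", "transcript")


DIALECTS: Dict[str, Gff3Dialect] = {
    "ensembl": Gff3Dialect("ensembl", biotype_keys=("biotype",)),
    "ncbi": Gff3Dialect("ncbi", biotype_keys=("gene_biotype",)),
    "augustus": Gff3Dialect("augustus", biotype_keys=()),
    "generic": Gff3Dialect("generic"),
}


def parse_gff3(path: PathLike, dialect: Union[str, Gff3Dialect] = "generic",
               species: str = "", label: str = "") -> AnnotationSet:
    """Read protein-coding gene models from GFF3.

    Only genes passing the dialect's biotype filter are retained; exon
    coordinates are converted from the on-disk 1-based inclusive convention
    to 0-based half-open. Transcripts without ``exon`` children fall back to
    their ``CDS`` children.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown GFF3 dialect {dialect!r}; "
                             f"choose from {sorted(DIALECTS)}") from None
    species = species or path.stem
    label = label or path.stem

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)

    known_parents = set()
    for ftype in ("gene",) + dialect.transcript_types:
        for feat in db.features_of_type(ftype):
            known_parents.add(feat.id)
    for feat in db.features_of_type(("exon", "CDS")):
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"{path}: {feat.featuretype} without Parent at "
                              f"{feat.seqid}:{feat.start}-{feat.end}")
        for p in parents:
            if p not in known_parents:
                raise FormatError(f"{path}: {feat.featuretype} references unknown "
                                  f"Parent {p!r}")

    genes: List[GeneModel] = []
    for gfeat in db.features_of_type("gene"):
        biotype = None
        for key in dialect.biotype_keys:
            if key in gfeat.attributes:
                biotype = gfeat.attributes[key][0]
                break
        if biotype is not None and biotype not in dialect.coding_values:
            continue
        transcripts: List[TranscriptModel] = []
        for tfeat in db.children(gfeat, featuretype=dialect.transcript_types):
            exon_feats = list(db.children(tfeat, featuretype="exon"))
            if not exon_feats:
                exon_feats = list(db.children(tfeat, featuretype="CDS"))
            if not exon_feats:
                raise FormatError(f"{path}: transcript {tfeat.id!r} has no "
                                  f"exon or CDS features")
            exons = tuple(
                GenomicInterval(chrom=e.seqid, start=e.start - 1, end=e.end,
                                strand=e.strand)
                for e in exon_feats
            )
            transcripts.append(TranscriptModel(id=tfeat.id, gene_id=gfeat.id,
                                               exons=exons))
        if not transcripts:
            continue
        genes.append(GeneModel(id=gfeat.id, species=species, transcripts=transcripts,
                               biotype=biotype or "protein_coding"))
    return AnnotationSet(label=label, species=species, genes=genes)


def write_gff3(annotation: AnnotationSet, path: PathLike,
               source: str = "orthoqc") -> None:
    """Write gene/mRNA/exon features, restoring 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for gene in sorted(annotation, key=lambda g: g.id):
        starts = [t.span[0] for t in gene.transcripts]
        ends = [t.span[1] for t in gene.transcripts]
        chrom = gene.transcripts[0].chrom
        strand = gene.transcripts[0].strand
        lines.append("\t".join([
            chrom, source, "gene", str(min(starts) + 1), str(max(ends)),
            ".", strand, ".", f"ID={gene.id};biotype={gene.biotype}",
        ]))
        for t in gene.transcripts:
            lines.append("\t".join([
                chrom, source, "mRNA", str(t.span[0] + 1), str(t.span[1]),
                ".", strand, ".", f"ID={t.id};Parent={gene.id}",
            ]))
            for i, e in enumerate(t.exons, 1):
                lines.append("\t".join([
                    chrom, source, "exon", str(e.start + 1), str(e.end),
                    ".", strand, ".", f"ID={t.id}.e{i};Parent={t.id}",
                ]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Newick species trees
# --------------------------------------------------------------------------

def parse_newick(source: PathLike, is_string: bool = False) -> SpeciesTree:
    """Read a rooted species tree; unlabeled internal nodes are auto-labeled
    ``node1``, ``node2``, ... in preorder (with a warning)."""
    try:
        if is_string:
            dtree = dendropy.Tree.get(data=str(source), schema="newick")
        else:
            dtree = dendropy.Tree.get(path=str(source), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise FormatError(f"bad Newick input: {exc}") from exc

    counter = [0]
    warned = [False]

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if not label:
                raise FormatError("leaf without label in Newick input")
        else:
            label = dnode.label or (dnode.taxon.label if dnode.taxon else None)
            if not label:
                counter[0] += 1
                label = f"node{counter[0]}"
                if not warned[0]:
                    warnings.warn("unlabeled internal node(s): auto-labeling as nodeK")
                    warned[0] = True
        node = TreeNode(label.replace(" ", "_"),
                        length=dnode.edge.length or 0.0)
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node

    root = convert(dtree.seed_node)
    leaves = [n.label for n in SpeciesTree(root).postorder() if n.is_leaf]
    if len(leaves) != len(set(leaves)):
        raise FormatError("duplicate leaf labels in Newick input")
    return SpeciesTree(root)


def write_newick(tree: SpeciesTree, path: PathLike, lengths: bool = True) -> None:
    Path(path).write_text(tree.newick(lengths=lengths) + "\n")


# --------------------------------------------------------------------------
# OrthoXML
# --------------------------------------------------------------------------

def parse_orthoxml(path: PathLike) -> HOGCollection:
    """Read nested hierarchical groups from an OrthoXML file.

    ``orthologGroup`` nesting is preserved; ``paralogGroup`` elements become
    child HOGs flagged as paralogous. Each root group's phyletic profile is
    computed from its members.
    """
    doc = etree.parse(str(path))
    ns = {"o": ORTHOXML_NS}
    gene_map: Dict[str, Tuple[str, str]] = {}
    for sp in doc.findall(".//o:species", ns):
        sp_name = sp.get("name")
        for gene in sp.findall(".//o:gene", ns):
            gene_map[gene.get("id")] = (sp_name, gene.get("geneId") or gene.get("protId"))

    counter = [0]

    def convert(elem, level: str) -> HOG:
        counter[0] += 1
        hid = elem.get("id") or f"HOG{counter[0]:05d}"
        is_paralog = etree.QName(elem).localname == "paralogGroup"
        for prop in elem.findall("o:property", ns):
            if prop.get("name") in ("TaxRange", "TaxId", "Level"):
                level = prop.get("value")
        members: List[Tuple[str, str]] = []
        children: List[HOG] = []
        for child in elem:
            tag = etree.QName(child).localname
            if tag == "geneRef":
                ref = child.get("id")
                if ref not in gene_map:
                    raise FormatError(f"{path}: geneRef {ref!r} not declared in "
                                      f"any species block")
                members.append(gene_map[ref])
            elif tag in ("orthologGroup", "paralogGroup"):
                sub = convert(child, level)
                children.append(sub)
                members.extend(sub.members)
        return HOG(id=hid, level=level, members=tuple(members),
                   children=tuple(children), paralog=is_paralog)

    roothogs = []
    groups = doc.find(".//o:groups", ns)
    if groups is not None:
        for top in groups.findall("o:orthologGroup", ns):
            roothogs.append(convert(top, level=""))
    return HOGCollection(roothogs=roothogs)


def write_orthoxml(hogs: HOGCollection, path: PathLike,
                   origin: str = "orthoqc") -> None:
    nsmap = {None: ORTHOXML_NS}
    root = etree.Element(f"{{{ORTHOXML_NS}}}orthoXML", nsmap=nsmap,
                         origin=origin, originVersion="0.1", version="0.3")
    # species blocks with integer gene ids
    by_species: Dict[str, List[str]] = {}
    for hog in hogs.roothogs:
        for sp, gid in hog.members:
            by_species.setdefault(sp, [])
            if gid not in by_species[sp]:
                by_species[sp].append(gid)
    ref_of: Dict[Tuple[str, str], str] = {}
    next_id = 1
    for sp in sorted(by_species):
        sp_el = etree.SubElement(root, f"{{{ORTHOXML_NS}}}species", name=sp,
                                 NCBITaxId="0")
        db_el = etree.SubElement(sp_el, f"{{{ORTHOXML_NS}}}database",
                                 name=origin, version="1")
        genes_el = etree.SubElement(db_el, f"{{{ORTHOXML_NS}}}genes")
        for gid in sorted(by_species[sp]):
            etree.SubElement(genes_el, f"{{{ORTHOXML_NS}}}gene", id=str(next_id),
                             geneId=gid, protId=gid)
            ref_of[(sp, gid)] = str(next_id)
            next_id += 1

    def emit(parent, hog: HOG) -> None:
        tag = "paralogGroup" if hog.paralog else "orthologGroup"
        el = etree.SubElement(parent, f"{{{ORTHOXML_NS}}}{tag}", id=hog.id)
        if hog.level and not hog.paralog:
            etree.SubElement(el, f"{{{ORTHOXML_NS}}}property", name="TaxRange",
                             value=hog.level)
        nested = set()
        for c in hog.children:
            nested.update(c.members)
            emit(el, c)
        for sp, gid in hog.members:
            if (sp, gid) not in nested:
                etree.SubElement(el, f"{{{ORTHOXML_NS}}}geneRef",
                                 id=ref_of[(sp, gid)])

    groups_el = etree.SubElement(root, f"{{{ORTHOXML_NS}}}groups")
    for hog in hogs.roothogs:
        emit(groups_el, hog)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


# --------------------------------------------------------------------------
# Pairwise orthologs, phyletic profiles, splice maps
# --------------------------------------------------------------------------

def parse_pairwise(path: PathLike, columns: Tuple[int, int] = (0, 1),
                   species_of: Optional[Mapping[str, str]] = None,
                   sep: str = "\t") -> OrthologPairs:
    """Read a pairwise-ortholog table (two protein-id columns; others ignored).

    Duplicate and order-swapped pairs collapse to one; a pair whose two ids
    belong to the same species raises a :class:`DataError` naming the line.
    """
    pairs = OrthologPairs(species_of=species_of)
    ca, cb = columns
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split(sep)
            try:
                a, b = fields[ca], fields[cb]
            except IndexError:
                raise FormatError(f"{path}:{lineno}: expected at least "
                                  f"{max(ca, cb) + 1} columns") from None
            try:
                pairs.add(a, b)
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return pairs


def write_pairwise(pairs: OrthologPairs, path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def parse_profile_tsv(path: PathLike) -> HOGCollection:
    """Read a phyletic-profile table (header: HOG id column, one column per
    species; cells are copy counts) into a profiles-only collection."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    hog_col = df.columns[0]
    species = list(df.columns[1:])
    profiles = {}
    for _, row in df.iterrows():
        profiles[str(row[hog_col])] = {sp: int(row[sp]) for sp in species
                                       if int(row[sp]) > 0}
    return HOGCollection(roothogs=[], profiles=profiles, species=species)


def write_profile_tsv(hogs: HOGCollection, path: PathLike) -> None:
    species = hogs.species
    rows = []
    for hid in sorted(hogs.profiles):
        prof = hogs.profiles[hid]
        rows.append([hid] + [int(prof.get(sp, 0)) for sp in species])
    df = pd.DataFrame(rows, columns=["HOG"] + list(species))
    df.to_csv(path, sep="\t", index=False)


def _common_prefix(ids: Sequence[str]) -> str:
    if not ids:
        return ""
    prefix = ids[0]
    for s in ids[1:]:
        while not s.startswith(prefix):
            prefix = prefix[:-1]
            if not prefix:
                return ""
    return prefix


def parse_splice(path: PathLike, delimiter: str = ";") -> SpliceMap:
    """Read an isoform-map file: one gene per line, isoform ids separated by
    ``delimiter``. If the line is tab-prefixed with a gene id that id is
    used; otherwise the gene id is the longest common prefix of the isoform
    ids (falling back to the first isoform id)."""
    smap = SpliceMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                gene, rest = line.split("\t", 1)
            else:
                gene, rest = "", line
            isoforms = [x for x in rest.split(delimiter) if x]
            if not isoforms:
                raise FormatError(f"{path}:{lineno}: no isoforms listed")
            if not gene:
                gene = _common_prefix(isoforms).rstrip("._-") or isoforms[0]
            if gene in smap:
                raise FormatError(f"{path}:{lineno}: duplicate gene {gene!r}")
            smap[gene] = isoforms
    return smap


def write_splice(smap: SpliceMap, path: PathLike, delimiter: str = ";") -> None:
    with open(path, "w") as fh:
        for gene in sorted(smap):
            fh.write(f"{gene}\t{delimiter.join(smap[gene])}\n")
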