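"""Discharge-record corpora, disease-gene association maps and vocabularies.

A *discharge record* is the ordered list of diagnosis codes (disease tokens)
assigned during one inpatient stay; it plays the role of a sentence in the
embedding models. A *gene map* associates disease tokens with the sets of
genes implicated by association studies, filtered at a p-value threshold.
The :class:`Vocabulary` indexes both kinds of token into one dense id space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DISEASE = "disease"
GENE = "gene"

__all__ = [
    "RecordCorpus",
    "GeneMap",
    "Vocabulary",
    "load_records",
    "write_records",
    "load_gene_map",
    "write_gene_map",
    "build_vocabulary",
    "attach_genes",
    "holdout_gene_map",
    "save_holdout",
]


class RecordCorpus:
    """An in-memory sequence of discharge records.

    Each record is a tuple of disease tokens in the order they were read;
    ordering encodes diagnosis priority and is never altered. The corpus is
    iterable any number of times with identical content.
    """

    def __init__(self, records: Iterable[Sequence[str]]):
        cleaned: list[tuple[str, ...]] = []
        for i, rec in enumerate(records):
            rec = tuple(rec)
            if len(rec) == 0:
                raise ValueError(f"record {i} is empty; records need >= 1 token")
            for tok in rec:
                if not tok or any(c.isspace() for c in tok):
                    raise ValueError(
                        f"record {i}: token {tok!r} is empty or contains whitespace"
                    )
            cleaned.append(rec)
        self._records = cleaned

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i):
        return self._records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RecordCorpus) and self._records == other._records

    def lengths(self) -> list[int]:
        return [len(r) for r in self._records]

    def __repr__(self) -> str:
        return f"RecordCorpus(n_records={len(self)})"


class GeneMap:
    """Disease token -> set of associated gene tokens.

    Diseases without genes are simply absent; looking one up returns the
    empty set. Provenance p-values are retained per (disease, gene) pair,
    keeping the smallest seen for duplicates.
    """

    def __init__(
        self,
        associations: Mapping[str, Iterable[str]] | None = None,
        pvalues: Mapping[tuple[str, str], float] | None = None,
    ):
        self._assoc: dict[str, frozenset[str]] = {}
        if associations:
            for d, genes in associations.items():
                gs = frozenset(genes)
                if gs:
                    self._assoc[d] = gs
        self._pvalues: dict[tuple[str, str], float] = dict(pvalues or {})

    def genes(self, disease: str) -> frozenset[str]:
        """Gene set of ``disease``; empty set if unannotated (never an error)."""
        return self._assoc.get(disease, frozenset())

    def pvalue(self, disease: str, gene: str) -> float | None:
        return self._pvalues.get((disease, gene))

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(self._assoc)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self._assoc.values():
            out |= gs
        return frozenset(out)

    def items(self):
        return self._assoc.items()

    def __len__(self) -> int:
        return len(self._assoc)

    def __contains__(self, disease: str) -> bool:
        return disease in self._assoc

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneMap) and self._assoc == other._assoc

    def __repr__(self) -> str:
        return f"GeneMap(n_diseases={len(self)}, n_genes={len(self.all_genes)})"


@dataclass
class Vocabulary:
    """Dense 0-based token index over disease and gene tokens.

    Diseases occupy ids ``[0, n_diseases)`` sorted by (count desc, token asc);
    genes follow with the same ordering. A gene's count is the total number
    of occurrences of its host diseases in the corpus (a gene is "seen" once
    per host-disease occurrence).
    """

    tokens: list[str]
    counts: np.ndarray  # int64, len == len(tokens)
    kinds: list[str]  # DISEASE or GENE per id
    token_to_id: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.token_to_id:
            self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        if len(self.tokens) != len(self.token_to_id):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def __getitem__(self, token: str) -> int:
        return self.token_to_id[token]

    @property
    def n_diseases(self) -> int:
        return sum(1 for k in self.kinds if k == DISEASE)

    def ids_of_kind(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == kind], dtype=np.int64)

    def kind(self, token: str) -> str:
        return self.kinds[self.token_to_id[token]]


def load_records(path: str | Path) -> RecordCorpus:
    """Read a discharge-record corpus: one record per line, tokens whitespace-separated.

    Blank lines are skipped (with a logged count), never fabricated into
    empty records.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as e:
        raise OSError(f"cannot read record file {path}: {e}") from e
    records: list[tuple[str, ...]] = []
    n_blank = 0
    for line in text.splitlines():
        toks = tuple(line.split())
        if not toks:
            n_blank += 1
            continue
        records.append(toks)
    if n_blank:
        logger.info("skipped %d blank line(s) in %s", n_blank, path)
    return RecordCorpus(records)


def write_records(corpus: RecordCorpus, path: str | Path) -> None:
    """Write a corpus back to disk, one space-joined record per line."""
    Path(path).write_text(
        "".join(" ".join(rec) + "\n" for rec in corpus), encoding="utf-8"
    )


def load_gene_map(path: str | Path, p_threshold: float = 1e-5) -> GeneMap:
    """Read a ``disease<TAB>gene<TAB>pvalue`` TSV, keeping rows with p < threshold.

    Duplicated (disease, gene) pairs are merged keeping the smallest p-value.
    The default threshold mirrors the conventional genome-wide suggestive
    cut-off of 1e-5 applied to association-catalog SNP hits.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as e:
        raise OSError(f"cannot read gene map {path}: {e}") from e
    if not lines:
        raise ValueError(f"{path}: empty file (expected a header row)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in ("disease", "gene", "pvalue"):
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
    i_d, i_g, i_p = header.index("disease"), header.index("gene"), header.index("pvalue")
    pvals: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) <= max(i_d, i_g, i_p):
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        d, g = parts[i_d].strip(), parts[i_g].strip()
        try:
            p = float(parts[i_p])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-numeric pvalue {parts[i_p]!r}") from e
        if p < p_threshold:
            key = (d, g)
            if key not in pvals or p < pvals[key]:
                pvals[key] = p
    assoc: dict[str, set[str]] = {}
    for (d, g) in pvals:
        assoc.setdefault(d, set()).add(g)
    return GeneMap(assoc, pvals)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    """Write a gene map as a 3-column TSV (pvalue 0.0 when provenance unknown)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tgene\tpvalue\n")
        for d in sorted(gene_map.diseases):
            for g in sorted(gene_map.genes(d)):
                p = gene_map.pvalue(d, g)
                fh.write(f"{d}\t{g}\t{0.0 if p is None else p:.6g}\n")


def build_vocabulary(
    corpus: RecordCorpus,
    gene_map: GeneMap | None = None,
    min_count: int = 5,
) -> Vocabulary:
    """Tally disease tokens, drop those below ``min_count``, and index genes.

    Every gene attached to a retained disease enters the vocabulary with
    kind=gene; its count equals the total corpus occurrences of its host
    diseases. Disease and gene namespaces must not collide.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for rec in corpus:
        for tok in rec:
            counts[tok] = counts.get(tok, 0) + 1
    if not counts:
        raise ValueError("empty corpus")
    kept = {t: c for t, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError(f"no disease token reaches min_count={min_count}")

    gene_counts: dict[str, int] = {}
    if gene_map is not None:
        for d, c in kept.items():
            for g in gene_map.genes(d):
                gene_counts[g] = gene_counts.get(g, 0) + c
        collision = set(kept) & set(gene_counts)
        if collision:
            raise ValueError(
                f"namespace collision: token(s) {sorted(collision)[:5]} appear "
                "as both disease and gene"
            )

    d_order = sorted(kept, key=lambda t: (-kept[t], t))
    g_order = sorted(gene_counts, key=lambda t: (-gene_counts[t], t))
    tokens = d_order + g_order
    arr = np.array([kept[t] for t in d_order] + [gene_counts[t] for t in g_order],
                   dtype=np.int64)
    kinds = [DISEASE] * len(d_order) + [GENE] * len(g_order)
    return Vocabulary(tokens=tokens, counts=arr, kinds=kinds)


def attach_genes(
    record: Sequence[str],
    gene_map: GeneMap,
    rng: np.random.Generator,
) -> list[tuple[str, tuple[str, ...]]]:
    """Attach each disease's gene set to its position as a freshly shuffled bag.

    The disease sequence itself is unchanged — genes never occupy sequence
    positions, so window offsets between diseases are unaffected. Gene order
    is re-drawn per occurrence to wash out any study-provenance ordering bias.
    """
    out: list[tuple[str, tuple[str, ...]]] = []
    for tok in record:
        genes = sorted(gene_map.genes(tok))
        if len(genes) > 1:
            genes = [genes[i] for i in rng.permutation(len(genes))]
        out.append((tok, tuple(genes)))
    return out


def holdout_gene_map(
    gene_map: GeneMap,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[GeneMap, GeneMap]:
    """Split annotated diseases into train/test by disease.

    ``round(fraction * n_annotated)`` diseases are sampled uniformly; their
    entire gene sets move to the test map. Train and test partition the
    original by disease.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    diseases = sorted(gene_map.diseases)
    n_test = round(fraction * len(diseases))
    if n_test == 0:
        raise ValueError("holdout too small: fraction selects 0 test diseases")
    test_idx = rng.choice(len(diseases), size=n_test, replace=False)
    test_set = {diseases[i] for i in test_idx}

    def _sub(keys: set[str]) -> GeneMap:
        assoc = {d: gene_map.genes(d) for d in keys}
        pv = {
            (d, g): gene_map.pvalue(d, g)
            for d in keys
            for g in gene_map.genes(d)
            if gene_map.pvalue(d, g) is not None
        }
        return GeneMap(assoc, pv)

    train = _sub(set(diseases) - test_set)
    test = _sub(test_set)
    return train, test


def save_holdout(
    train: GeneMap,
    test: GeneMap,
    out_dir: str | Path,
    seed: int,
    fraction: float,
) -> None:
    """Persist a holdout split as two TSVs plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gene_map(train, out_dir / "train_gene_map.tsv")
    write_gene_map(test, out_dir / "test_gene_map.tsv")
    manifest = {
        "seed": seed,
        "fraction": fraction,
        "n_train_diseases": len(train),
        "n_test_diseases": len(test),
    }
    (out_dir / "holdout_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
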