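"""Shared fixtures and hand-rolled helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from atlastax.io_formats import BlastHit, SequenceRecord

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

BASES = "ACGT"


def make_hit(
    qid: str,
    sid: str,
    qseq: str,
    sseq: str,
    bitscore: float,
    qstart: int = 1,
    sstart: int = 1,
) -> BlastHit:
    """Build a consistent BlastHit from aligned strings."""
    pairs = [(a, b) for a, b in zip(qseq, sseq)]
    matches = sum(a == b and a != "-" for a, b in pairs)
    mismatch = sum(a != b and a != "-" and b != "-" for a, b in pairs)
    gapopen = 0
    prev_gap = False
    for a, b in pairs:
        gap = a == "-" or b == "-"
        if gap and not prev_gap:
            gapopen += 1
        prev_gap = gap
    q_ungapped = qseq.replace("-", "")
    s_ungapped = sseq.replace("-", "")
    return BlastHit(
        qseqid=qid, sseqid=sid,
        pident=100.0 * matches / len(qseq), length=len(qseq),
        mismatch=mismatch, gapopen=gapopen,
        qstart=qstart, qend=qstart + len(q_ungapped) - 1,
        sstart=sstart, send=sstart + len(s_ungapped) - 1,
        evalue=1e-5, bitscore=bitscore, qseq=qseq, sseq=sseq,
    )


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitutions to a different base."""
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            out[i] = BASES[(BASES.index(ch) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def oracle_bild(counts, alpha=0.5, background=0.25) -> float:
    """Closed-form BILD score via math.lgamma, independent of the package."""
    a = [alpha] * 4
    big_a = sum(a)
    n = sum(counts)
    log_marg = math.lgamma(big_a) - math.lgamma(big_a + n)
    for ai, ci in zip(a, counts):
        log_marg += math.lgamma(ai + ci) - math.lgamma(ai)
    log_marg /= math.log(2.0)
    log_back = sum(ci * math.log2(background) for ci in counts)
    return log_marg - log_back


def oracle_column_counts(rows: list[str], col: int) -> tuple[int, int, int, int]:
    """Count A/C/G/T in one column of a list of gapped rows."""
    counts = [0, 0, 0, 0]
    for row in rows:
        ch = row[col]
        if ch in BASES:
            counts[BASES.index(ch)] += 1
    return tuple(counts)


def oracle_detect(query_row: str, hit_rows: list[str], min_gain: float = 20.0):
    """Independent re-scoring of the outlier split search.

    Plain-Python loops over columns and cuts: per-cut column-local gain
    sum(max(0, bild(top)+bild(rest)-bild(all))), internal cut chosen by the
    per-top-row normalised gain (smallest index on ties), then the
    min_gain-gated decision among top-k / whole-list / empty. Returns
    (k, score).
    """
    K = len(hit_rows)
    C = len(query_row)
    all_rows = [query_row] + hit_rows
    association = sum(
        oracle_bild(oracle_column_counts(all_rows, c)) for c in range(C)
    )
    deltas = []
    for k in range(1, K):
        top = [query_row] + hit_rows[:k]
        rest = hit_rows[k:]
        delta = 0.0
        for c in range(C):
            dcol = (
                oracle_bild(oracle_column_counts(top, c))
                + oracle_bild(oracle_column_counts(rest, c))
                - oracle_bild(oracle_column_counts(all_rows, c))
            )
            delta += max(0.0, dcol)
        deltas.append(delta)
    best_k, best_norm, best_delta = 0, -math.inf, -math.inf
    for i, d in enumerate(deltas):
        norm = d / (i + 2.0)
        if norm > best_norm:
            best_k, best_norm, best_delta = i + 1, norm, d
    if best_delta > min_gain:
        return best_k, best_delta
    if association > min_gain:
        return K, association
    return 0, max(best_delta, association)


@pytest.fixture(scope="session")
def clade_world():
    """The standard six-group synthetic world plus parsed hits."""
    from atlastax import (
        CladeSpec,
        generate_queries,
        generate_reference,
        parse_blast_tabular,
        simulate_hit_table,
    )
    import tempfile, pathlib

    spec = CladeSpec()
    refs, taxonomy, ref_truth = generate_reference(spec)
    queries, query_truth = generate_queries(refs, ref_truth, spec)
    tmp = pathlib.Path(tempfile.mkdtemp())
    hit_path = tmp / "hits.tsv"
    simulate_hit_table(queries, refs, hit_path)
    hits = parse_blast_tabular(hit_path)
    return {
        "spec": spec, "refs": refs, "taxonomy": taxonomy,
        "ref_truth": ref_truth, "queries": queries,
        "query_truth": query_truth, "hits": hits, "hit_path": hit_path,
    }
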