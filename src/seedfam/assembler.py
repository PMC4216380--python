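"""A small de Bruijn-graph transcriptome assembler with an explicit word size.

The word size (k-mer length) decides whether near-identical paralogs merge
into one tangled subgraph or separate into distinct contigs: two transcripts
are assembled independently exactly when every exact substring they share is
shorter than k.  The assembler therefore exposes k as a first-class sweep
parameter, together with bubble size, minimum contig length and paired-end
scaffolding, so the effect of the word size on paralog capture can be
studied directly.

Graph model: canonical k-mers (lexicographic minimum of a k-mer and its
reverse complement) with coverage counts; adjacency by (k-1)-overlap in both
orientations.  Contigs are maximal non-branching paths after tip removal and
bubble popping.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class AssemblyParams:
    """Assembler parameter set; the user-facing knobs are word_size (k),
    bubble_size, min_contig_length and paired scaffolding."""

    word_size: int = 23
    bubble_size: int = 50
    min_contig_length: int = 100
    use_pairs: bool = False
    scaffold: bool = False
    tip_length_limit: int | None = None  # nodes; default 2k
    min_link_pairs: int = 3

    def __post_init__(self) -> None:
        if not (11 <= self.word_size <= 64):
            raise ValueError("word size must lie in [11, 64]")
        if self.bubble_size < 0:
            raise ValueError("bubble size must be >= 0")
        if self.min_contig_length < self.word_size:
            raise ValueError("min contig length must be >= word size")

    @property
    def tip_limit(self) -> int:
        return self.tip_length_limit if self.tip_length_limit is not None else 2 * self.word_size


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n50: int
    contig_count: int
    total_bases: int


@dataclass
class Assembly:
    params: AssemblyParams
    contigs: list[Contig]
    stats: AssemblyStats


class DeBruijnGraph:
    """Canonical k-mer graph with coverage counts."""

    def __init__(self, k: int, counts: dict[str, int]):
        self.k = k
        self.counts = counts

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def coverage(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    # oriented navigation ---------------------------------------------------

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if canonical(suffix + b) in self.counts]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in "ACGT" if canonical(b + prefix) in self.counts]


def build_graph(reads: Iterable, k: int) -> DeBruijnGraph:
    """Count canonical k-mers over a read set.

    ``reads`` may be sequence strings or objects with a ``.sequence``
    attribute.  k-mers containing N are skipped.
    """
    counts: dict[str, int] = {}
    any_long_enough = False
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        n = len(seq)
        if n < k:
            continue
        any_long_enough = True
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    if not any_long_enough:
        raise ValueError(f"no read is at least k={k} bases long")
    return DeBruijnGraph(k, counts)


# ---------------------------------------------------------------------------
# unitigs


def _unitigs(graph: DeBruijnGraph) -> list[tuple[str, list[str]]]:
    """Maximal non-branching oriented paths.

    Returns (sequence, canonical node list) per unitig; each canonical k-mer
    appears in exactly one unitig.
    """
    k = graph.k
    visited: set[str] = set()
    out: list[tuple[str, list[str]]] = []

    def extendable(a: str, b: str) -> bool:
        # unitig edge a->b: a has exactly one successor, b exactly one predecessor
        return len(graph.successors(a)) == 1 and len(graph.predecessors(b)) == 1

    for start in sorted(graph.counts):
        if start in visited:
            continue
        # walk backward then forward from `start` in its canonical orientation
        path = [start]
        seen_local = {start}
        cur = start
        while True:
            preds = graph.predecessors(cur)
            if len(preds) != 1:
                break
            p = preds[0]
            if canonical(p) in seen_local or not extendable(p, cur):
                break
            if canonical(p) in visited:
                break
            path.append(p)
            seen_local.add(canonical(p))
            cur = p
        path.reverse()
        cur = path[-1]
        while True:
            succs = graph.successors(cur)
            if len(succs) != 1:
                break
            s = succs[0]
            if canonical(s) in seen_local or not extendable(cur, s):
                break
            if canonical(s) in visited:
                break
            path.append(s)
            seen_local.add(canonical(s))
            cur = s
        seq = path[0] + "".join(p[-1] for p in path[1:])
        nodes = [canonical(p) for p in path]
        visited.update(nodes)
        out.append((seq, nodes))
    return out


def _mean_cov(graph: DeBruijnGraph, nodes: Sequence[str]) -> float:
    return sum(graph.counts[n] for n in nodes) / len(nodes)


def simplify_graph(
    graph: DeBruijnGraph,
    tip_length_limit: int | None = None,
    bubble_size: int = 50,
    max_rounds: int = 20,
) -> DeBruijnGraph:
    """Remove short low-coverage dead-end tips and pop simple bubbles.

    A tip is a unitig that dead-ends on one side, attaches to a branch point
    on the other, spans at most ``tip_length_limit`` nodes (default 2k) and
    has lower mean coverage than the best sibling branch at the junction.
    A bubble is a pair of unitigs sharing their single predecessor and single
    successor whose lengths differ by at most ``bubble_size`` bases; the
    lower-coverage path is absorbed (ties keep the lexicographically smaller
    sequence).  Rounds of tip removal and bubble popping run to a fixpoint.
    """
    tip_limit = tip_length_limit if tip_length_limit is not None else 2 * graph.k
    for _ in range(max_rounds):
        changed = False
        units = _unitigs(graph)

        # --- tips
        doomed: set[str] = set()
        for seq, nodes in units:
            k = graph.k
            first, last = seq[: k], seq[-k:]
            preds = graph.predecessors(first)
            succs = graph.successors(last)
            dead_start = len(preds) == 0
            dead_end = len(succs) == 0
            if dead_start == dead_end:  # isolated or internal: not a tip
                continue
            if len(nodes) > tip_limit:
                continue
            junction = succs if dead_start else preds
            # sibling branches at the junction: other neighbours of the junction node
            jnode = junction[0]
            if dead_start:
                siblings = [p for p in graph.predecessors(jnode) if canonical(p) != canonical(last)]
            else:
                siblings = [s for s in graph.successors(jnode) if canonical(s) != canonical(first)]
            if not siblings:
                continue
            best_sibling = max(graph.coverage(s) for s in siblings)
            if _mean_cov(graph, nodes) < best_sibling:
                doomed.update(nodes)
        if doomed:
            for n in doomed:
                graph.counts.pop(n, None)
            changed = True
            units = _unitigs(graph)

        # --- bubbles
        k = graph.k
        groups: dict[tuple, list[tuple[str, list[str]]]] = {}
        for seq, nodes in units:
            first, last = seq[:k], seq[-k:]
            preds = graph.predecessors(first)
            succs = graph.successors(last)
            if len(preds) == 1 and len(succs) == 1:
                key_f = (canonical(preds[0]), canonical(succs[0]))
                groups.setdefault(key_f, []).append((seq, nodes))
        doomed = set()
        for members in groups.values():
            if len(members) < 2:
                continue
            members = sorted(
                members, key=lambda m: (-_mean_cov(graph, m[1]), m[0])
            )
            keep_seq, keep_nodes = members[0]
            for seq, nodes in members[1:]:
                if abs(len(seq) - len(keep_seq)) <= bubble_size:
                    doomed.update(nodes)
        if doomed:
            for n in doomed:
                graph.counts.pop(n, None)
            changed = True

        if not changed:
            break
    return graph


def _oriented_output(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def extract_contigs(graph: DeBruijnGraph, min_contig_length: int) -> list[Contig]:
    """Spell maximal non-branching paths; drop short contigs; deterministic
    ordering (descending length, then lexicographic)."""
    rows = []
    for seq, nodes in _unitigs(graph):
        if len(seq) < min_contig_length:
            continue
        rows.append((_oriented_output(seq), _mean_cov(graph, nodes)))
    rows.sort(key=lambda r: (-len(r[0]), r[0]))
    return [
        Contig(f"contig_{i}", seq, round(cov, 3)) for i, (seq, cov) in enumerate(rows, start=1)
    ]


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """N50 (length L such that contigs >= L hold at least half the bases),
    contig count and total bases."""
    if not contigs:
        return AssemblyStats(0, 0, 0)
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    for L in lengths:
        acc += L
        if 2 * acc >= total:
            return AssemblyStats(L, len(lengths), total)
    return AssemblyStats(lengths[-1], len(lengths), total)


# ---------------------------------------------------------------------------
# paired-end scaffolding


def _seed_index(contigs: Sequence[Contig], seed: int) -> dict[str, list]:
    index: dict[str, list] = {}
    for ci, c in enumerate(contigs):
        seq = c.sequence
        for i in range(0, len(seq) - seed + 1):
            index.setdefault(seq[i : i + seed], []).append((ci, i))
    return index


def _place_read(seq: str, index: Mapping[str, list], seed: int):
    """Vote-based unique placement: (contig index, start, strand) or None."""
    votes: dict[tuple[int, int, int], int] = {}
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for i in range(0, len(s) - seed + 1, seed):
            for ci, pos in index.get(s[i : i + seed], ()):
                key = (ci, pos - i, strand)
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    best = max(votes.values())
    winners = [k for k, v in votes.items() if v == best]
    if len(winners) != 1:
        return None
    return winners[0]


def scaffold(
    contigs: Sequence[Contig],
    pairs: Sequence[tuple],
    min_link_pairs: int = 3,
    seed: int = 21,
) -> list[Contig]:
    """Join contigs supported by consistently oriented read pairs.

    The insert-size distribution is estimated (median +/- MAD) from pairs
    whose mates both place uniquely on one contig.  Contig pairs linked by at
    least ``min_link_pairs`` spanning pairs in a single consistent relative
    orientation are joined with an N-run of the estimated gap length
    (floor 1).  Without usable spanning pairs the input is returned unchanged.
    """
    if not contigs or not pairs:
        return list(contigs)
    index = _seed_index(contigs, seed)

    inserts: list[int] = []
    links: dict[tuple, list[int]] = {}
    for p in pairs:
        r1 = p[0] if isinstance(p[0], str) else p[0].sequence
        r2 = p[1] if isinstance(p[1], str) else p[1].sequence
        pl1 = _place_read(r1, index, seed)
        pl2 = _place_read(r2, index, seed)
        if pl1 is None or pl2 is None:
            continue
        c1, s1, st1 = pl1
        c2, s2, st2 = pl2
        if c1 == c2:
            if st1 != st2:  # innie pair on one contig
                left = min(s1, s2)
                right = max(s1 + len(r1), s2 + len(r2))
                inserts.append(right - left)
            continue
        # spanning pair: orient so the pair reads point toward the gap
        # normalise: key (min contig, max contig, relative orientation)
        if st1 == st2:
            rel = -1  # contigs in opposite orientation
        else:
            rel = 1
        a, b = sorted((c1, c2))
        # distance from each mate to the contig end it points at
        if c1 == a:
            da = (len(contigs[c1]) - s1 - len(r1)) if st1 == 1 else s1
            db = s2 if st2 == -1 else (len(contigs[c2]) - s2 - len(r2))
        else:
            da = (len(contigs[c2]) - s2 - len(r2)) if st2 == 1 else s2
            db = s1 if st1 == -1 else (len(contigs[c1]) - s1 - len(r1))
        # fragment = read1 + da + gap + db + read2
        links.setdefault((a, b, rel), []).append(da + db + len(r1) + len(r2))

    if not inserts or not links:
        return list(contigs)
    med_insert = statistics.median(inserts)

    joined: set[int] = set()
    out: list[Contig] = []
    # deterministic order: strongest links first
    for (a, b, rel), dists in sorted(
        links.items(), key=lambda kv: (-len(kv[1]), kv[0])
    ):
        if len(dists) < min_link_pairs:
            continue
        # orientation consistency: a competing orientation with as much support blocks the join
        other = links.get((a, b, -rel), [])
        if len(other) >= min_link_pairs:
            continue
        if a in joined or b in joined:
            continue
        gap = max(1, int(round(med_insert - statistics.median(dists))))
        gap = min(gap, max(1, int(med_insert)))
        right = contigs[b].sequence if rel == 1 else reverse_complement(contigs[b].sequence)
        seq = contigs[a].sequence + "N" * gap + right
        cov = (contigs[a].mean_kmer_coverage + contigs[b].mean_kmer_coverage) / 2
        out.append(Contig("scaffold", seq, round(cov, 3)))
        joined.update((a, b))
    for i, c in enumerate(contigs):
        if i not in joined:
            out.append(c)
    rows = sorted(out, key=lambda c: (-len(c), c.sequence))
    return [
        Contig(f"contig_{i}", c.sequence, c.mean_kmer_coverage)
        for i, c in enumerate(rows, start=1)
    ]


# ---------------------------------------------------------------------------
# top-level assembly


def assemble(
    reads: Iterable,
    params: AssemblyParams,
    pairs: Sequence[tuple] | None = None,
) -> Assembly:
    """QC'd reads -> simplified graph -> contigs (-> scaffolds) -> stats."""
    graph = build_graph(reads, params.word_size)
    simplify_graph(graph, params.tip_limit, params.bubble_size)
    contigs = extract_contigs(graph, params.min_contig_length)
    if params.scaffold and params.use_pairs and pairs:
        contigs = scaffold(contigs, pairs, params.min_link_pairs)
    return Assembly(params, contigs, assembly_stats(contigs))


def multi_k_assemble(
    reads: Iterable,
    k_list: Sequence[int],
    params: AssemblyParams = AssemblyParams(),
    pairs: Sequence[tuple] | None = None,
) -> dict[int, Assembly]:
    """Assemble once per distinct word size; failures are recorded, not fatal."""
    reads = [r if isinstance(r, str) else r.sequence for r in reads]
    out: dict[int, Assembly] = {}
    for k in dict.fromkeys(k_list):  # dedup, keep order
        try:
            p = AssemblyParams(
                word_size=k,
                bubble_size=params.bubble_size,
                min_contig_length=max(params.min_contig_length, k),
                use_pairs=params.use_pairs,
                scaffold=params.scaffold,
                tip_length_limit=params.tip_length_limit,
                min_link_pairs=params.min_link_pairs,
            )
            out[k] = assemble(reads, p, pairs)
        except ValueError:
            out[k] = Assembly(params, [], AssemblyStats(0, 0, 0))
    return out


def union_contigs(assemblies: Mapping[int, Assembly], identity: float = 0.99) -> list[Contig]:
    """Merge contigs across word sizes, deduplicating near-identical sequences.

    Two contigs are redundant when their identity over the aligned span is at
    least ``identity`` (strand-insensitive); the longer representative wins.
    """
    import edlib

    pool: list[Contig] = []
    for k in sorted(assemblies):
        pool.extend(assemblies[k].contigs)
    pool.sort(key=lambda c: (-len(c), c.sequence))
    kept: list[Contig] = []
    for c in pool:
        redundant = False
        for K in kept:
            span = min(len(c), len(K))
            max_dist = int(span * (1 - identity))
            r = edlib.align(c.sequence, K.sequence, mode="HW", task="distance", k=max_dist)
            if r["editDistance"] == -1:
                r = edlib.align(
                    reverse_complement(c.sequence), K.sequence, mode="HW",
                    task="distance", k=max_dist,
                )
            if r["editDistance"] != -1:
                redundant = True
                break
        if not redundant:
            kept.append(c)
    return [
        Contig(f"contig_{i}", c.sequence, c.mean_kmer_coverage)
        for i, c in enumerate(kept, start=1)
    ]


def write_fasta(contigs: Iterable[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} cov={c.mean_kmer_coverage}\n{c.sequence}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (id, sequence) pairs."""
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
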