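"""Internal pairwise-placement kernel shared by consensus and polishing.

All overhang reads in an end-group abut the chromosome terminus, so every
read is placed against a template starting at column 0 (edlib SHW mode:
query aligned to a template prefix). The kernel turns a set of placements
into per-column vote profiles over {A,C,G,T,-,N}; insertion columns relative
to the template are keyed by (template_pos, slot).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib

_EDLIB_CIGAR_RE = re.compile(r"(\d+)([=XID])")

# column_vote tie-break order; N handled separately (never wins unless alone)
_VOTE_ORDER = {"-": 0, "A": 1, "C": 2, "G": 3, "T": 4}


def edlib_ops(query: str, target: str, mode: str = "SHW") -> list[tuple[str, int]]:
    """Align query to target and return (op, length) pairs.

    Ops: '=' match, 'X' mismatch (both consume query and target), 'I' extra
    query base, 'D' extra target base. In SHW mode the query is aligned to a
    prefix of the target.
    """
    res = edlib.align(query, target, mode=mode, task="path")
    cigar = res["cigar"]
    if cigar is None:
        return []
    return [(m.group(2), int(m.group(1))) for m in _EDLIB_CIGAR_RE.finditer(cigar)]


def column_vote(column_bases: Counter | dict[str, int]) -> str:
    """Majority vote over one alignment column.

    The most frequent symbol wins; ties break by the fixed order
    - < A < C < G < T. N never wins unless it is the only symbol present.
    """
    counts = Counter(column_bases)
    if not counts:
        raise ValueError("column_vote: empty column")
    non_n = {s: c for s, c in counts.items() if s != "N" and c > 0}
    if not non_n:
        return "N"
    best = max(non_n.items(), key=lambda kv: (kv[1], -_VOTE_ORDER.get(kv[0], 9)))
    return best[0]


@dataclass
class Profile:
    """Vote profile of a read group placed on a template."""

    template: str
    votes: list[Counter]  # one per template column, symbols A/C/G/T/-/N
    ins: dict[tuple[int, int], Counter]  # (template_pos, slot) -> base votes
    junction_cov: list[int]  # reads spanning the junction before column t
    cov: list[int] = field(default_factory=list)  # reads covering column t

    def __post_init__(self) -> None:
        if not self.cov:
            self.cov = [sum(v.values()) for v in self.votes]


def _k_limit(query: str, band_bp: int | None) -> int:
    """Edit-distance cap for a placement: the band plus a 10% divergence
    allowance. Bounds edlib's O(k*n) search; -1 means unbounded."""
    if band_bp is None:
        return -1
    return band_bp + len(query) // 10


def _place_one(
    read: str, template: str, votes, ins, junction_cov, mode: str, band_bp: int | None
) -> float:
    """Place one read against the template and add its column votes.

    ``mode`` "anchored" forces the placement to start at column 0 (SHW:
    reads abut the terminus by construction); "infix" lets the read start
    anywhere (HW), for support recounts where a read's true placement may be
    interior. Returns the placement identity (0 when unalignable); the
    caller may have already decided to skip low-identity reads.
    """
    tlen = len(template)
    query = read if len(read) <= tlen else read[: tlen + 16]
    k = _k_limit(query, band_bp)
    if mode == "anchored":
        res = edlib.align(query, template, mode="SHW", task="path", k=k)
        tstart = 0
    else:
        res = edlib.align(query, template, mode="HW", task="path", k=k)
        if not res["locations"] or res["locations"][0][0] is None:
            tstart = 0
        else:
            tstart = res["locations"][0][0]
    cigar = res["cigar"]
    if cigar is None:
        return 0.0
    ops = [(m.group(2), int(m.group(1))) for m in _EDLIB_CIGAR_RE.finditer(cigar)]
    # trailing I ops are read bases past the template end, not insertions
    while ops and ops[-1][0] == "I":
        ops.pop()
    ident = 1.0 - res["editDistance"] / max(1, len(query))
    tpos = tstart
    rpos = 0
    for op, n in ops:
        if op in "=X":
            for _ in range(n):
                votes[tpos][query[rpos]] += 1
                tpos += 1
                rpos += 1
        elif op == "D":  # read lacks these template bases
            for _ in range(n):
                votes[tpos]["-"] += 1
                tpos += 1
        else:  # 'I': read has extra bases before template column tpos
            for j in range(n):
                ins[(tpos, j)][query[rpos]] += 1
                rpos += 1
    for t in range(tstart, tpos):
        junction_cov[t] += 1
    return ident


def _placement_identity(read: str, template: str, mode: str, band_bp: int | None) -> float:
    tlen = len(template)
    query = read if len(read) <= tlen else read[: tlen + 16]
    emode = "SHW" if mode == "anchored" else "HW"
    res = edlib.align(query, template, mode=emode, task="distance", k=_k_limit(query, band_bp))
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / max(1, len(query))


def build_profile(
    template: str,
    reads: list[str],
    mode: str = "anchored",
    min_identity: float | None = None,
    band_bp: int | None = 50,
) -> Profile:
    """Place every read against the template and collect column votes.

    Reads whose placement identity falls below ``min_identity`` are left out
    of the profile entirely — they do not belong at this placement and would
    only poison the votes (greedy elongation picks them up later).
    ``band_bp`` bounds the edit-distance search (see _k_limit).
    """
    from collections import defaultdict

    tlen = len(template)
    votes = [Counter() for _ in range(tlen)]
    ins: dict[tuple[int, int], Counter] = defaultdict(Counter)
    junction_cov = [0] * (tlen + 1)
    for read in reads:
        if not read:
            continue
        if (
            min_identity is not None
            and _placement_identity(read, template, mode, band_bp) < min_identity
        ):
            continue
        _place_one(read, template, votes, ins, junction_cov, mode, band_bp)
    return Profile(template=template, votes=votes, ins=dict(ins), junction_cov=junction_cov)


def consensus_from_profile(
    profile: Profile,
    min_depth_for_vote: int = 1,
    keep_template_below_depth: bool = False,
) -> tuple[str, list[int]]:
    """Call a consensus sequence (and per-base depth) from a vote profile.

    Columns with coverage >= ``min_depth_for_vote`` are replaced by their
    vote winner ('-' deletes the column); below that depth the template base
    is kept when ``keep_template_below_depth`` (polishing) or kept as-is with
    its low depth (initial consensus, where the template is itself a read).
    Insertion columns are emitted when, among reads spanning the junction,
    the inserted base wins a strict vote against '-'.
    """
    template = profile.template
    out: list[str] = []
    depth: list[int] = []
    tlen = len(template)
    for t in range(tlen + 1):
        jcov = profile.junction_cov[t]
        if jcov >= max(min_depth_for_vote, 1):
            slot = 0
            while (t, slot) in profile.ins:
                base_votes = Counter(profile.ins[(t, slot)])
                absent = jcov - sum(base_votes.values())
                if absent > 0:
                    base_votes["-"] += absent
                winner = column_vote(base_votes)
                if winner == "-":
                    break
                out.append(winner)
                depth.append(sum(profile.ins[(t, slot)].values()))
                slot += 1
        if t == tlen:
            break
        cov = profile.cov[t]
        if cov >= min_depth_for_vote and cov > 0:
            winner = column_vote(profile.votes[t])
            if winner == "-":
                continue
            out.append(winner)
            depth.append(cov)
        elif keep_template_below_depth or cov == 0:
            out.append(template[t])
            depth.append(cov)
        else:
            winner = column_vote(profile.votes[t])
            if winner == "-":
                continue
            out.append(winner)
            depth.append(cov)
    return "".join(out), depth


def identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences in [0, 1]."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))
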