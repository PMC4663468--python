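"""Structural detection of transposable elements in genomic windows.

Each detector looks for the class-defining termini and flanking repeats:

* LTR retrotransposon — two direct repeats (100–3000 bp, >= 80 % identity,
  1–15 kb apart), each starting ``TG`` and ending ``CA``, flanked by an
  identical 4–6 bp target-site duplication (TSD).
* Helitron — 5' terminus ``TC`` and 3' terminus ``CTAG``, each terminus
  carrying an adjacent hairpin (two >= 11 bp arms that are reverse
  complements of each other), the element inserted between host ``a`` and
  ``t`` nucleotides (no TSD).
* CACTA — terminal inverted repeats (TIRs) >= 10 bp whose outer ends begin
  ``CACTA``, with a 3 bp TSD.
* MULE — TIRs >= 40 bp with a 9–10 bp TSD.
* hAT — TIRs >= 10 bp with an 8 bp TSD.

Coordinates in results are 1-based inclusive within the supplied window and
denote the element body (terminal repeat to terminal repeat); TSDs lie just
outside the reported span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class TEAnnotation:
    element_class: str               # LTR | Helitron | CACTA | MULE | hAT
    start: int                       # 1-based inclusive, window coordinates
    end: int
    tsd: str = ""
    chromosome: str = ""
    details: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TEParams:
    ltr_min_len: int = 100
    ltr_max_len: int = 3000
    ltr_min_identity: float = 0.80
    ltr_min_sep: int = 1000          # distance between repeat starts
    ltr_max_sep: int = 15000
    ltr_seed_k: int = 12
    helitron_min_len: int = 200
    helitron_max_len: int = 20000
    hairpin_min_arm: int = 11
    hairpin_window: int = 30
    cacta_min_tir: int = 10
    mule_min_tir: int = 40
    hat_min_tir: int = 10
    tir_min_len: int = 100           # minimum DNA-transposon element length
    tir_max_len: int = 20000
    tir_seed_k: int = 10


DEFAULT_TE_PARAMS = TEParams()


def detect_te_elements(window_seq: str, element_class: str,
                       params: TEParams | None = None) -> list[TEAnnotation]:
    """Run one class-specific structural detector over a nucleotide window."""
    params = params or DEFAULT_TE_PARAMS
    seq = window_seq.upper()
    detectors = {
        "LTR": _detect_ltr,
        "Helitron": _detect_helitron,
        "CACTA": _detect_cacta,
        "MULE": lambda s, p: _detect_tir_class(s, p, "MULE", p.mule_min_tir, (9, 10)),
        "hAT": lambda s, p: _detect_tir_class(s, p, "hAT", p.hat_min_tir, (8,)),
    }
    if element_class not in detectors:
        raise ValueError(f"unknown element class {element_class!r}")
    hits = detectors[element_class](seq, params)
    return _dedupe(hits)


def _dedupe(hits: list[TEAnnotation]) -> list[TEAnnotation]:
    """Keep the longest call among overlapping ones; sort by position."""
    kept: list[TEAnnotation] = []
    for h in sorted(hits, key=lambda h: (-h.length, h.start)):
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# LTR retrotransposons

def _detect_ltr(seq: str, p: TEParams) -> list[TEAnnotation]:
    n = len(seq)
    if n < p.ltr_min_sep + p.ltr_min_len:
        return []
    k = p.ltr_seed_k
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)

    seen = set()
    hits = []
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                d = j - i
                if d < p.ltr_min_sep - 200 or d > p.ltr_max_sep + 200:
                    continue
                ext = _extend_direct(seq, i, j, k)
                if ext is None or ext in seen:
                    continue
                seen.add(ext)
                ann = _refine_ltr(seq, ext, d, p)
                if ann is not None:
                    hits.append(ann)
    return hits


def _extend_direct(seq, i, j, k, xdrop: int = 15):
    """X-drop ungapped extension of a seeded direct-repeat match.

    Returns (i0, i1) span of the first repeat copy (0-based inclusive); the
    second copy sits at the same offset ``j - i``.
    """
    d = j - i
    n = len(seq)
    # extend right from the seed end
    score = 0.0
    best = 0.0
    best_r = k - 1
    r = k
    while j + r < n and score > best - xdrop:
        score += 1.0 if seq[i + r] == seq[j + r] else -2.0
        if score > best:
            best, best_r = score, r
        r += 1
    # extend left from the seed start
    score = 0.0
    best = 0.0
    best_l = 0
    l = 1
    while i - l >= 0 and score > best - xdrop:
        score += 1.0 if seq[i - l] == seq[j - l] else -2.0
        if score > best:
            best, best_l = score, l
        l += 1
    return (i - best_l, i + best_r)


def _refine_ltr(seq, ext, d, p):
    i0, i1 = ext
    n = len(seq)
    best = None
    for s in range(max(0, i0 - 8), min(i0 + 9, n)):
        if not (seq[s:s + 2] == "TG" and seq[s + d:s + d + 2] == "TG"):
            continue
        for e in range(min(i1 + 8, n - 1), max(i1 - 9, s + 1), -1):
            if not (seq[e - 1:e + 1] == "CA" and seq[e + d - 1:e + d + 1] == "CA"):
                continue
            length = e - s + 1
            if not (p.ltr_min_len <= length <= p.ltr_max_len):
                continue
            if not (p.ltr_min_sep <= d <= p.ltr_max_sep):
                continue
            matches = sum(seq[s + t] == seq[s + d + t] for t in range(length))
            if matches / length < p.ltr_min_identity:
                continue
            tsd = ""
            for t in (6, 5, 4):
                if s - t >= 0 and seq[s - t:s] == seq[e + d + 1:e + d + 1 + t]:
                    tsd = seq[s - t:s]
                    break
            if not tsd:
                continue
            cand = TEAnnotation(
                element_class="LTR", start=s + 1, end=e + d + 1, tsd=tsd,
                details={"ltr5": (s + 1, e + 1), "ltr3": (s + d + 1, e + d + 1),
                         "ltr_identity": matches / length},
            )
            if best is None or cand.length > best.length:
                best = cand
        if best is not None:
            break
    return best


# ---------------------------------------------------------------------------
# Helitrons

def _hairpin_in(region: str, min_arm: int):
    """Hairpin (arm, rc(arm)) with arm >= min_arm inside ``region``; returns
    the one starting closest to the region start, or None."""
    m = len(region)
    best = None
    for k in range(min(m // 2, min_arm + 6), min_arm - 1, -1):
        for i in range(m - 2 * k + 1):
            if best is not None and i >= best[0]:
                break
            arm = region[i:i + k]
            rc = _rc(arm)
            for j in range(i + k, m - k + 1):
                if region[j:j + k] == rc:
                    if best is None or i < best[0]:
                        best = (i, k, j)
                    break
    return best


def _detect_helitron(seq: str, p: TEParams) -> list[TEAnnotation]:
    n = len(seq)
    hits = []
    # candidate 3' termini: CTAG followed by host T, hairpin just upstream
    ends = []
    pos = seq.find("CTAG")
    while pos != -1:
        e = pos + 3
        if e + 1 < n and seq[e + 1] == "T":
            region = seq[max(0, pos - p.hairpin_window):pos]
            if _hairpin_in(region, p.hairpin_min_arm):
                ends.append(e)
        pos = seq.find("CTAG", pos + 1)
    if not ends:
        return []
    # candidate 5' termini: host A then TC, hairpin just downstream; the
    # hairpin abuts the terminus, so prefer the start whose hairpin is
    # nearest (several upstream A-TC contexts can share one hairpin window)
    starts = []
    pos = seq.find("TC", 1)
    while pos != -1:
        if seq[pos - 1] == "A":
            region = seq[pos + 2:pos + 2 + p.hairpin_window]
            hp = _hairpin_in(region, p.hairpin_min_arm)
            if hp is not None:
                starts.append((pos, hp[0]))
        pos = seq.find("TC", pos + 1)
    for e in ends:
        compatible = [(off, s) for s, off in starts
                      if p.helitron_min_len <= e - s + 1 <= p.helitron_max_len]
        if not compatible:
            continue
        _, s = min(compatible)
        hits.append(TEAnnotation(
            element_class="Helitron", start=s + 1, end=e + 1,
            details={"host": (seq[s - 1].lower(), seq[e + 1].lower())},
        ))
    return hits


# ---------------------------------------------------------------------------
# CACTA

def _tir_run(seq, s, e) -> int:
    """Length of the exact inverted-repeat run pairing seq[s+t] with seq[e-t]."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    t = 0
    while s + t < e - t and seq[s + t] == comp.get(seq[e - t], "?"):
        t += 1
    return t


def _detect_cacta(seq: str, p: TEParams) -> list[TEAnnotation]:
    n = len(seq)
    starts = []
    pos = seq.find("CACTA")
    while pos != -1:
        starts.append(pos)
        pos = seq.find("CACTA", pos + 1)
    ends = []
    pos = seq.find("TAGTG")
    while pos != -1:
        ends.append(pos + 4)
        pos = seq.find("TAGTG", pos + 1)
    hits = []
    for s in starts:
        for e in ends:
            length = e - s + 1
            if not (p.tir_min_len <= length <= p.tir_max_len):
                continue
            tir = _tir_run(seq, s, e)
            if tir < p.cacta_min_tir:
                continue
            if s - 3 < 0 or e + 4 > n or seq[s - 3:s] != seq[e + 1:e + 4]:
                continue
            hits.append(TEAnnotation(
                element_class="CACTA", start=s + 1, end=e + 1,
                tsd=seq[s - 3:s], details={"tir_len": tir},
            ))
    return hits


# ---------------------------------------------------------------------------
# MULE / hAT (generic TIR + TSD classes)

def _detect_tir_class(seq: str, p: TEParams, label: str, min_tir: int,
                      tsd_lens: tuple[int, ...]) -> list[TEAnnotation]:
    n = len(seq)
    k = min(p.tir_seed_k, min_tir)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    hits = []
    seen = set()
    for i in range(n - k + 1):
        rc = _rc(seq[i:i + k])
        for q in index.get(rc, ()):
            # left arm starts at i, right arm ends at q + k - 1
            e = q + k - 1
            if e - i + 1 < p.tir_min_len or e - i + 1 > p.tir_max_len or q <= i + k:
                continue
            s = i
            # extend outward
            while s - 1 >= 0 and e + 1 < n and seq[s - 1] == comp.get(seq[e + 1], "?"):
                s -= 1
                e += 1
            if (s, e) in seen:
                continue
            seen.add((s, e))
            # a TSD whose outer bases happen to base-pair gets swallowed by
            # the extension; trim back a few bases while validating
            for trim in range(0, 5):
                s2, e2 = s + trim, e - trim
                if _tir_run(seq, s2, e2) < min_tir:
                    break
                tsd = ""
                for t in tsd_lens:
                    if s2 - t >= 0 and seq[s2 - t:s2] == seq[e2 + 1:e2 + 1 + t]:
                        tsd = seq[s2 - t:s2]
                        break
                if tsd:
                    hits.append(TEAnnotation(
                        element_class=label, start=s2 + 1, end=e2 + 1, tsd=tsd,
                        details={"tir_len": _tir_run(seq, s2, e2)},
                    ))
                    break
    return hits


# ---------------------------------------------------------------------------
# carried-fragment typing

FRAGMENT_TYPES = {1: "whole", 2: "three_prime", 3: "five_prime", 4: "middle"}
_TERMINUS_FRACTION = 0.10


def classify_te_carried_fragment(carried_cds: str, parent_cds: str,
                                 terminus_fraction: float = _TERMINUS_FRACTION) -> int:
    """Type the gene fragment carried by a TE against its parent CDS.

    Type 1 = whole gene; 2 = 3'-region only; 3 = 5'-region only; 4 = internal
    region touching neither terminus. "Touching" a terminus means the carried
    region aligns into the first/last ``terminus_fraction`` of the parent CDS.
    The carried copy may be on either strand.
    """
    if not carried_cds or not parent_cds:
        raise ValueError("empty sequence")
    span = _best_span(parent_cds, carried_cds)
    if span is None:
        raise ValueError("carried fragment does not align to the parent gene")
    f1, f2 = span
    touch5 = f1 <= terminus_fraction
    touch3 = f2 >= 1.0 - terminus_fraction
    if touch5 and touch3:
        return 1
    if touch3:
        return 2
    if touch5:
        return 3
    return 4


def _best_span(parent: str, fragment: str):
    """Fractional interval of ``parent`` covered by the best local alignment
    of ``fragment`` (either strand), or None if no credible alignment."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    best = None
    for frag in (fragment.upper(), _rc(fragment.upper())):
        alns = aligner.align(parent.upper(), frag)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best.score:
            best = aln
    if best is None or best.score < 2.0 * 20:  # < 20 matched bases: noise
        return None
    blocks = best.aligned[0]
    lo = int(blocks[0][0])
    hi = int(blocks[-1][1])
    L = len(parent)
    return lo / L, hi / L
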