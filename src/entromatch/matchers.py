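"""Instrumented exact string-matching algorithms.

Seven classical single-pattern matchers over the sliding-window contract:
brute force (BF), Morris-Pratt (MP), Knuth-Morris-Pratt (KMP),
Apostolico-Crochemore (AC), Quick Search (QS), Boyer-Moore (BM) and
Horspool (HOR).  Every matcher reports all (possibly overlapping)
occurrences of the pattern plus the number of character comparisons (CC)
performed during the scan phase.

The CC metric counts each pattern-character vs text-character equality
test exactly once, whether it succeeds or fails.  Preprocessing work
(failure functions, shift tables) compares pattern characters with
pattern characters and is therefore *not* counted: the metric measures
how much of the text an algorithm has to touch.  No sentinel or guard
tricks are used, so counts reflect the textbook formulations.

Offsets are 0-based.  Characters are compared by exact code-point
equality (case-sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

__all__ = [
    "SearchOutcome",
    "ALGORITHM_IDS",
    "match",
    "naive_oracle",
    "register_algorithm",
]

#: The matcher function contract: (text, pattern) -> (occurrences, comparisons).
#: Called only with 1 <= len(pattern) <= len(text).
MatcherFn = Callable[[str, str], Tuple[List[int], int]]


@dataclass(frozen=True)
class SearchOutcome:
    """Result of one algorithm on one (text, pattern) pair.

    Attributes
    ----------
    algorithm : str
        Algorithm identifier (one of :data:`ALGORITHM_IDS`).
    n, m : int
        Text and pattern length in characters.
    occurrences : tuple of int
        Strictly increasing 0-based start offsets of all exact matches.
    comparisons : int
        Scan-phase pattern-vs-text character comparison count (CC).
    """

    algorithm: str
    n: int
    m: int
    occurrences: Tuple[int, ...]
    comparisons: int


# ---------------------------------------------------------------------------
# the seven matchers


def _bf(text: str, pat: str) -> Tuple[List[int], int]:
    """Naive left-to-right scan: every window, compare until mismatch."""
    n, m = len(text), len(pat)
    occ: List[int] = []
    comp = 0
    for s in range(n - m + 1):
        j = 0
        while j < m:
            comp += 1
            if text[s + j] != pat[j]:
                break
            j += 1
        else:
            occ.append(s)
    return occ, comp


def _mp_table(pat: str) -> List[int]:
    # mpNext[i] = length of the longest proper border of pat[:i]; mpNext[0] = -1
    m = len(pat)
    nxt = [0] * (m + 1)
    nxt[0] = -1
    i, t = 0, -1
    while i < m:
        while t > -1 and pat[i] != pat[t]:
            t = nxt[t]
        i += 1
        t += 1
        nxt[i] = t
    return nxt


def _kmp_table(pat: str) -> List[int]:
    # Strong failure function: a border is rejected when it would retry the
    # same mismatching character.
    m = len(pat)
    nxt = [0] * (m + 1)
    nxt[0] = -1
    i, t = 0, -1
    while i < m:
        while t > -1 and pat[i] != pat[t]:
            t = nxt[t]
        i += 1
        t += 1
        if i < m and pat[i] == pat[t]:
            nxt[i] = nxt[t]
        else:
            nxt[i] = t
    return nxt


def _search_with_failure(text: str, pat: str, nxt: List[int]) -> Tuple[List[int], int]:
    n, m = len(text), len(pat)
    occ: List[int] = []
    comp = 0
    i = 0  # matched prefix length
    for j in range(n):
        while i > -1:
            comp += 1
            if text[j] == pat[i]:
                break
            i = nxt[i]
        i += 1
        if i >= m:
            occ.append(j - m + 1)
            i = nxt[i]
    return occ, comp


def _mp(text: str, pat: str) -> Tuple[List[int], int]:
    """Morris-Pratt: failure-function shifts, never re-reads matched text."""
    return _search_with_failure(text, pat, _mp_table(pat))


def _kmp(text: str, pat: str) -> Tuple[List[int], int]:
    """Knuth-Morris-Pratt: MP with the strong (mismatch-aware) failure table."""
    return _search_with_failure(text, pat, _kmp_table(pat))


def _bm_bad_char(pat: str) -> Dict[str, int]:
    m = len(pat)
    return {pat[i]: m - 1 - i for i in range(m - 1)}


def _bm_suffixes(pat: str) -> List[int]:
    m = len(pat)
    suff = [0] * m
    suff[m - 1] = m
    g = m - 1
    f = 0
    for i in range(m - 2, -1, -1):
        if i > g and suff[i + m - 1 - f] < i - g:
            suff[i] = suff[i + m - 1 - f]
        else:
            if i < g:
                g = i
            f = i
            while g >= 0 and pat[g] == pat[g + m - 1 - f]:
                g -= 1
            suff[i] = f - g
    return suff


def _bm_good_suffix(pat: str) -> List[int]:
    m = len(pat)
    suff = _bm_suffixes(pat)
    gs = [m] * m
    j = 0
    for i in range(m - 1, -1, -1):
        if suff[i] == i + 1:
            while j < m - 1 - i:
                if gs[j] == m:
                    gs[j] = m - 1 - i
                j += 1
    for i in range(m - 1):
        gs[m - 1 - suff[i]] = m - 1 - i
    return gs


def _bm(text: str, pat: str) -> Tuple[List[int], int]:
    """Boyer-Moore: right-to-left scan, bad-character + good-suffix shifts."""
    n, m = len(text), len(pat)
    bc = _bm_bad_char(pat)
    gs = _bm_good_suffix(pat)
    occ: List[int] = []
    comp = 0
    j = 0
    while j <= n - m:
        i = m - 1
        while i >= 0:
            comp += 1
            if pat[i] != text[i + j]:
                break
            i -= 1
        if i < 0:
            occ.append(j)
            j += gs[0]
        else:
            j += max(gs[i], bc.get(text[i + j], m) - m + 1 + i)
    return occ, comp


def _hor(text: str, pat: str) -> Tuple[List[int], int]:
    """Horspool: right-to-left scan, shift by the window's last text character."""
    n, m = len(text), len(pat)
    bc = {pat[i]: m - 1 - i for i in range(m - 1)}
    occ: List[int] = []
    comp = 0
    j = 0
    while j <= n - m:
        i = m - 1
        while i >= 0:
            comp += 1
            if pat[i] != text[j + i]:
                break
            i -= 1
        if i < 0:
            occ.append(j)
        j += bc.get(text[j + m - 1], m)
    return occ, comp


def _qs(text: str, pat: str) -> Tuple[List[int], int]:
    """Quick Search: left-to-right scan, shift by the character after the window."""
    n, m = len(text), len(pat)
    bc = {pat[i]: m - i for i in range(m)}
    occ: List[int] = []
    comp = 0
    j = 0
    while j <= n - m:
        i = 0
        while i < m:
            comp += 1
            if pat[i] != text[j + i]:
                break
            i += 1
        else:
            occ.append(j)
        if j + m >= n:
            break
        j += bc.get(text[j + m], m + 1)
    return occ, comp


def _ac(text: str, pat: str) -> Tuple[List[int], int]:
    """Apostolico-Crochemore: a^l-factorization scan with prefix memory.

    Write the pattern as ``a^l b u`` where ``a`` is its first character,
    ``l`` the length of the initial run of ``a`` and ``b != a``.  Within an
    attempt, comparisons run in the order ``l, l+1, ..., m-1`` and only then
    ``0, ..., l-1``; the variable ``k`` remembers how many of the leading
    ``a`` characters are already known to match, so they are never
    re-compared.  Shifts distinguish three cases on the forward stop
    position ``i`` (immediate stop, interior mismatch, complete forward
    match); interior shifts consult the positions where ``a^l b`` reoccurs
    inside the pattern, which is the only way an occurrence can start
    inside the forward-verified region.
    """
    n, m = len(text), len(pat)
    occ: List[int] = []
    comp = 0
    a = pat[0]
    ell = 1
    while ell < m and pat[ell] == a:
        ell += 1

    if ell == m:
        # Unary pattern a^m: slide by one, remembering the matched prefix.
        j = 0
        k = 0
        while j <= n - m:
            while k < m:
                comp += 1
                if text[j + k] != a:
                    break
                k += 1
            else:
                occ.append(j)
            j += 1
            k = max(0, k - 1)
        return occ, comp

    b = pat[ell]
    # Positions s > ell where the head a^l b re-occurs inside the pattern:
    # the only interior start positions a shift may not jump over.
    heads = [
        s
        for s in range(ell + 1, m - ell)
        if pat[s + ell] == b and all(pat[s + t] == a for t in range(ell))
    ]

    j = 0
    k = 0  # leading characters of the window known to equal a (k <= ell)
    i = ell  # pat[ell:i] is known to match text[j+ell:j+i]
    while j <= n - m:
        while i < m:
            comp += 1
            if text[i + j] != pat[i]:
                break
            i += 1
        else:
            while k < ell:
                comp += 1
                if text[j + k] != a:
                    break
                k += 1
            else:
                occ.append(j)
        if i == ell:
            # No forward progress: shift one; one known leading a survives less.
            j += 1
            k = max(0, k - 1)
        else:
            # text[j+ell:j+i] == pat[ell:i] rules out every start below
            # i-ell except re-occurrences of the head a^l b.
            shift = max(ell + 1, i - ell)
            for h in heads:
                if h + ell <= i - 1:
                    shift = min(shift, h)
                    break
            new_k = 0
            for t in range(ell):
                p = shift + t
                if p < k:
                    known = a
                elif ell <= p < i:
                    known = pat[p]
                else:
                    break
                if known != a:
                    break
                new_k += 1
            j += shift
            k = new_k
            i = ell
    return occ, comp


# ---------------------------------------------------------------------------
# registry and public entry points

_REGISTRY: Dict[str, MatcherFn] = {
    "BF": _bf,
    "MP": _mp,
    "KMP": _kmp,
    "AC": _ac,
    "QS": _qs,
    "BM": _bm,
    "HOR": _hor,
}

#: The closed set of built-in algorithm identifiers, in campaign order.
ALGORITHM_IDS: Tuple[str, ...] = ("BF", "MP", "KMP", "AC", "QS", "BM", "HOR")


def register_algorithm(algorithm_id: str, fn: MatcherFn) -> None:
    """Plug-in point: add a matcher under a new identifier.

    The function must honour the :data:`MatcherFn` contract and count
    scan-phase pattern-vs-text comparisons the same way the built-ins do,
    otherwise its CC numbers are not comparable.  Built-in identifiers
    cannot be overwritten.
    """
    if algorithm_id in _REGISTRY:
        raise ValueError(f"algorithm id {algorithm_id!r} already registered")
    _REGISTRY[algorithm_id] = fn


def available_algorithms() -> Tuple[str, ...]:
    """All registered algorithm identifiers (built-ins first)."""
    return tuple(_REGISTRY)


def match(algorithm: str, text: str, pattern: str) -> SearchOutcome:
    """Run one matcher and report occurrences plus the CC count.

    Parameters
    ----------
    algorithm : str
        Identifier of a registered matcher (``BF``, ``MP``, ``KMP``, ``AC``,
        ``QS``, ``BM``, ``HOR`` or a plug-in).
    text, pattern : str
        The text to scan and the nonempty pattern to find.

    Returns
    -------
    SearchOutcome
        All occurrence offsets (possibly overlapping) and the number of
        scan-phase character comparisons.  If the pattern is longer than
        the text there is nothing to scan: no occurrences, zero
        comparisons.
    """
    if not isinstance(text, str) or not isinstance(pattern, str):
        raise TypeError("text and pattern must be strings")
    if len(pattern) == 0:
        raise ValueError("pattern must have length >= 1")
    try:
        fn = _REGISTRY[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm id {algorithm!r}") from None
    n, m = len(text), len(pattern)
    if m > n:
        return SearchOutcome(algorithm, n, m, (), 0)
    occ, comp = fn(text, pattern)
    return SearchOutcome(algorithm, n, m, tuple(occ), comp)


def naive_oracle(text: str, pattern: str) -> List[int]:
    """All match offsets by exhaustive window check (test reference only)."""
    if not isinstance(text, str) or not isinstance(pattern, str):
        raise TypeError("text and pattern must be strings")
    if len(pattern) == 0:
        raise ValueError("pattern must have length >= 1")
    m = len(pattern)
    return [s for s in range(len(text) - m + 1) if text[s : s + m] == pattern]
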