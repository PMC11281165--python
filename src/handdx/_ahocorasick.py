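"""Aho-Corasick multi-pattern string matching.

A trie over the dictionary with BFS-built failure links and output links:
one pass over the text reports every occurrence of every dictionary string,
which is what makes dictionary-scale entity matching practical compared to
repeated naive substring search.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator


class AhoCorasick:
    """Automaton over a fixed set of nonempty pattern strings."""

    def __init__(self, patterns: Iterable[str]) -> None:
        # node 0 is the root; nodes are parallel lists
        self._next: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[str]] = [[]]
        self._patterns: set[str] = set()
        for pat in patterns:
            self._insert(pat)
        self._build_links()

    def _insert(self, pattern: str) -> None:
        if not pattern:
            raise ValueError("empty pattern")
        if pattern in self._patterns:
            return
        self._patterns.add(pattern)
        node = 0
        for ch in pattern:
            nxt = self._next[node].get(ch)
            if nxt is None:
                nxt = len(self._next)
                self._next.append({})
                self._fail.append(0)
                self._out.append([])
                self._next[node][ch] = nxt
            node = nxt
        self._out[node].append(pattern)

    def _build_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._next[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._next[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._next[f]:
                    f = self._fail[f]
                self._fail[child] = self._next[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                # inherit outputs reachable through the failure chain
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def __len__(self) -> int:
        return len(self._patterns)

    def __contains__(self, pattern: str) -> bool:
        return pattern in self._patterns

    def find_all(self, text: str) -> Iterator[tuple[int, int, str]]:
        """Yield every occurrence as (start, end, pattern), end exclusive,
        in order of the match's end position."""
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._next[node]:
                node = self._fail[node]
            node = self._next[node].get(ch, 0)
            for pat in self._out[node]:
                yield (i + 1 - len(pat), i + 1, pat)


def naive_find_all(patterns: Iterable[str], text: str) -> list[tuple[int, int, str]]:
    """Brute-force O(n*m) reference: every occurrence of every pattern."""
    hits = []
    for pat in set(patterns):
        start = text.find(pat)
        while start != -1:
            hits.append((start, start + len(pat), pat))
            start = text.find(pat, start + 1)
    return sorted(hits, key=lambda h: (h[1], h[0]))
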