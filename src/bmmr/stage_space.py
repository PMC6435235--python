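"""Stage structure for two-sex union models.

The population is classified into juvenile males ``m1``, single adult males
``m2``, juvenile females ``f1``, single adult females ``f2``, and mated
unions.  A union stage ``u_i`` is one adult male plus a harem of ``i``
females; monogamy is the special case of a single union stage ``u_1`` (one
male, one female).  With maximum harem size ``h`` there are ``4 + h`` stages,
ordered ``(m1, m2, f1, f2, u_1, ..., u_h)``.

Because union stages bundle several individuals, conservation checks and
sex-ratio computations need accounting vectors that say how many individuals
(and of which sex) one unit of each stage contains.  :class:`StageSpace`
carries those vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StageSpace", "make_stage_space"]


@dataclass(frozen=True)
class StageSpace:
    """Ordered stage labels plus per-stage individual content.

    Attributes
    ----------
    labels : tuple of str
        Stage names in model order: ``(m1, m2, f1, f2, u1, ..., uh)``.
        For ``h = 1`` the single union stage is labelled ``u``.
    s : int
        Number of stages, ``4 + h``.
    h : int
        Maximum harem size.
    multiplicity : ndarray
        Individuals per unit of each stage (1 for singles, ``1 + i`` for
        union ``u_i``).
    adult_males : ndarray
        Adult males per unit of each stage (1 for ``m2`` and every union).
    adult_females : ndarray
        Adult females per unit of each stage (1 for ``f2``, ``i`` for
        ``u_i``).
    """

    labels: tuple[str, ...]
    s: int
    h: int
    multiplicity: np.ndarray = field(repr=False)
    adult_males: np.ndarray = field(repr=False)
    adult_females: np.ndarray = field(repr=False)

    # fixed positions of the named single stages
    M1, M2, F1, F2 = 0, 1, 2, 3

    def union_index(self, i: int) -> int:
        """Index of union stage ``u_i`` (harem of ``i`` females)."""
        if not 1 <= i <= self.h:
            raise ValueError(f"union size {i} outside 1..{self.h}")
        return 3 + i

    @property
    def union_slice(self) -> slice:
        """Slice selecting all union stages."""
        return slice(4, self.s)

    @property
    def adults(self) -> np.ndarray:
        """Adults (either sex) per unit of each stage."""
        return self.adult_males + self.adult_females


def make_stage_space(h: int) -> StageSpace:
    """Build the stage space for maximum harem size ``h``.

    Parameters
    ----------
    h : int
        Maximum harem size, >= 1.  ``h = 1`` gives the 5-stage monogamy
        space; ``h > 1`` appends one union stage per harem size.

    Returns
    -------
    StageSpace

    Examples
    --------
    >>> sp = make_stage_space(3)
    >>> sp.labels
    ('m1', 'm2', 'f1', 'f2', 'u1', 'u2', 'u3')
    >>> sp.multiplicity.tolist()
    [1, 1, 1, 1, 2, 3, 4]
    """
    if isinstance(h, bool) or not isinstance(h, (int, np.integer)):
        raise TypeError(f"harem size h must be an integer, got {h!r}")
    if h < 1:
        raise ValueError(f"harem size h must be >= 1, got {h}")
    h = int(h)

    if h == 1:
        union_labels = ("u",)
    else:
        union_labels = tuple(f"u{i}" for i in range(1, h + 1))
    labels = ("m1", "m2", "f1", "f2") + union_labels
    s = 4 + h

    multiplicity = np.ones(s, dtype=np.int64)
    adult_males = np.zeros(s, dtype=np.int64)
    adult_females = np.zeros(s, dtype=np.int64)
    adult_males[1] = 1
    adult_females[3] = 1
    for i in range(1, h + 1):
        j = 3 + i
        multiplicity[j] = 1 + i
        adult_males[j] = 1
        adult_females[j] = i

    return StageSpace(
        labels=labels,
        s=s,
        h=h,
        multiplicity=multiplicity,
        adult_males=adult_males,
        adult_females=adult_females,
    )
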