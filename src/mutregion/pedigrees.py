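"""Programmatic example pedigrees.

`five_generation_pedigree` builds a five-generation pedigree whose latest
generation of ten individuals forms the genotyped input, with a configurable
number of diseased individuals among them; the disease descends from a single
diseased founder through an unbroken chain of diseased ancestors (dominant,
single origin).  The genotyped generation's members are cousins several
meioses apart, which is the regime the detector targets: closely related
individuals whose pedigree is unknown to the program.
"""

from __future__ import annotations

from .simulate import Member, Pedigree


def five_generation_pedigree(n_diseased: int = 2) -> Pedigree:
    """Five generations; ten genotyped individuals in the last one.

    ``n_diseased`` in 1..4 of the ten are diseased; the rest are unaffected
    cousins.  Only the last generation is marked ``in_output``.
    """
    if not 1 <= n_diseased <= 4:
        raise ValueError("n_diseased must be in 1..4")
    M = []

    def add(mid, father, mother, sex, dis, out=False):
        M.append(Member(mid, father, mother, sex, dis, out))

    # G1: the diseased founder couple at the top
    add("g1a", None, None, "M", True)
    add("g1b", None, None, "F", False)
    # G2: two children, one diseased; both marry founders
    add("g2a", "g1a", "g1b", "M", True)
    add("g2a_sp", None, None, "F", False)
    add("g2b", "g1a", "g1b", "F", False)
    add("g2b_sp", None, None, "M", False)
    # G3: the carrier line branches into two diseased sibs
    add("g3a", "g2a", "g2a_sp", "M", True)
    add("g3a_sp", None, None, "F", False)
    add("g3b", "g2a", "g2a_sp", "F", True)
    add("g3b_sp", None, None, "M", False)
    add("g3c", "g2b_sp", "g2b", "M", False)
    add("g3c_sp", None, None, "F", False)
    # G4: each G3 couple has a carrier-line child and a normal child
    add("g4a", "g3a", "g3a_sp", "M", True)
    add("g4a_sp", None, None, "F", False)
    add("g4b", "g3a", "g3a_sp", "F", False)
    add("g4b_sp", None, None, "M", False)
    add("g4c", "g3b_sp", "g3b", "M", True)
    add("g4c_sp", None, None, "F", False)
    add("g4d", "g3b_sp", "g3b", "F", False)
    add("g4d_sp", None, None, "M", False)
    add("g4e", "g3c", "g3c_sp", "M", False)
    add("g4e_sp", None, None, "F", False)
    # G5: ten genotyped individuals, n_diseased of them diseased
    dis_flags = [True, n_diseased >= 3, True, n_diseased >= 4] + [False] * 6
    if n_diseased == 1:
        dis_flags[2] = False
    add("i01", "g4a", "g4a_sp", "M", dis_flags[0], out=True)
    add("i02", "g4a", "g4a_sp", "F", dis_flags[1], out=True)
    add("i03", "g4c", "g4c_sp", "M", dis_flags[2], out=True)
    add("i04", "g4c", "g4c_sp", "F", dis_flags[3], out=True)
    add("i05", "g4b_sp", "g4b", "M", False, out=True)
    add("i06", "g4b_sp", "g4b", "F", False, out=True)
    add("i07", "g4d_sp", "g4d", "M", False, out=True)
    add("i08", "g4d_sp", "g4d", "F", False, out=True)
    add("i09", "g4e", "g4e_sp", "M", False, out=True)
    add("i10", "g4e", "g4e_sp", "F", False, out=True)
    return Pedigree(M)
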