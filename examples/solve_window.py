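"""Phase a single window of genotypes by hand.

Builds two tiny window instances — one solvable purely by Clark's rule, one
needing a sharing pair between two normals — plus an instance where a normal
individual unavoidably carries the diseased center haplotype (Type II false),
and prints the inferred haplotypes.
"""

from mutregion import MrhipInstance, hap_str, run_mrhip


def show(title, diseased, normal):
    print(f"\n{title}")
    print(f"  diseased: {diseased}   normal: {normal}")
    out = run_mrhip(MrhipInstance.from_strings(diseased, normal))
    print(f"  status: {out.status.value}")
    if out.is_true:
        print(f"  center haplotype (carried by every diseased): {hap_str(out.center)}")
        for label, (h1, h2) in zip(diseased + normal, out.pairs):
            print(f"    {label} -> {hap_str(h1)} / {hap_str(h2)}")
        print(f"  distinct haplotypes DH = {out.dh} "
              f"(lower DH = more parsimonious = stronger sharing signal)")


show("Clark-rule solving", ["10211", "12221", "10221"], ["10121"])
show("Sharing pair between two unsolved normals",
     ["12110", "11210"], ["21111", "11121"])
show("Type II: a normal must carry the center", ["111", "121"], ["112", "102"])
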