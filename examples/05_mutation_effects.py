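"""How charge-altering point mutations shift the similarity index.

Mutations are modeled as charge edits on the wild-type geometry (chi
consumes only charges and distances).  Removing a positive charge near
the specific contacts lowers chi (more frustration, slower predicted
association); flipping an acidic residue to a basic one raises it.
"""

import tempfile

from searchkin import assign_charges, read_structure
from searchkin.fixtures import make_toy_complex, toy_complex_spec
from searchkin.frustration import mutation_effect

with tempfile.TemporaryDirectory() as tmp:
    paths = make_toy_complex(toy_complex_spec("patch-overlap"), tmp)
    model = assign_charges(read_structure(paths["pdb"]))

    for mutations in ("A:K5Q", "A:E9K", "A:K5Q,A:E9K"):
        rep = mutation_effect(model, mutations, pin_contacts=True)
        print(f"{mutations:<14} chi {rep['chi_wt']:.4f} -> "
              f"{rep['chi_mut']:.4f}   delta = {rep['delta_chi']:+.4f} "
              f"({rep['relative_change']:+.1%} vs wild type)")

print()
print("K5Q deletes a +1 inside the patch -> chi drops; E9K flips a -1 at",
      "the rim to +1 -> chi rises. The contact set is pinned to the wild",
      "type so delta-chi isolates the electrostatic effect.")
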