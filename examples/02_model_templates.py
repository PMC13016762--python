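"""Build the rate-matrix templates for a hierarchical character.

Shows the four families on the feather codings: plain Mk, embedded
dependency (no hidden states), structured Markov (hidden liabilities), and
the hidden rates expansion — and the 21-model grid they form.
"""

import asekit as ak
from asekit.models import feather_hierarchy

print("Mk 6-state: ER/SYM/ARD parameters:",
      [ak.mk_template(6, s).n_params for s in ("ER", "SYM", "ARD")])

h2 = feather_hierarchy(2)  # feathers > pennaceous (coding 2)
space, bd = ak.amalgamate_ed(h2, "ER", variant="BD")
print("ED-BD states:", space.model_states,
      "| scales->pennaceous forbidden:", bd.index[0, 2] == 0)

space, smm = ak.amalgamate_smm(h2, "ER", variant="ind")
print("SMM states:", space.model_states,
      "| hidden 'scales' preimages:", [space.model_states[i] for i in space.preimages(0)])

space, hrm = ak.expand_hrm(ak.mk_template(6, "ARD"), n_categories=3)
print("HRM(3) on 6 states:", space.n_model, "model states,", hrm.n_params, "parameters")
# 94 free parameters -- as many as tips on a 94-taxon tree, the classic
# overparameterized case excluded from AICc ranking.

grid = ak.model_grid()
print("experiment grid:", len(grid), "models; x3 trees =", 3 * len(grid), "combinations")
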