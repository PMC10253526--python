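# Default water-radiolysis reaction network with dissolved molecular oxygen
# treated as a continuum solute (one uniform concentration, never an evolving
# field).
#
# Units in this file:
#   D_nm2_per_ns   diffusion coefficient; 1 nm^2/ns == 1e-9 m^2/s
#   k_per_M_per_s  bimolecular rate constant in M^-1 s^-1 (converted to
#                  M^-1 ns^-1 on load)
#
# Same-species convention (A + A -> P): the listed k is the *event* rate
# constant, i.e. d[A]/dt = -2 k [A]^2 and d[P]/dt = +k [A]^2.  Tabulated
# "observed" decay constants (k_obs with d[A]/dt = -k_obs [A]^2) are halved
# before being entered here.
#
# Values are standard diffusion-controlled water-chemistry constants at
# neutral pH / 25 C; they are configuration, not code — edit or override
# freely.  Implied H2O reactants/products are omitted (element balance is
# checked modulo water).
species:
  - {name: OH,    D_nm2_per_ns: 2.8,  category: i,   charge: 0,  n_H: 1, n_O: 1}
  - {name: H3O+,  D_nm2_per_ns: 9.46, category: i,   charge: 1,  n_H: 3, n_O: 1}
  - {name: H,     D_nm2_per_ns: 5.0,  category: i,   charge: 0,  n_H: 1, n_O: 0}
  - {name: e_aq-, D_nm2_per_ns: 4.9,  category: i,   charge: -1, n_H: 0, n_O: 0}
  - {name: H2,    D_nm2_per_ns: 4.8,  category: ii,  charge: 0,  n_H: 2, n_O: 0}
  - {name: H2O2,  D_nm2_per_ns: 2.3,  category: ii,  charge: 0,  n_H: 2, n_O: 2}
  - {name: OH-,   D_nm2_per_ns: 5.3,  category: ii,  charge: -1, n_H: 1, n_O: 1}
  - {name: HO2,   D_nm2_per_ns: 2.3,  category: iii, charge: 0,  n_H: 1, n_O: 2}
  - {name: O2-,   D_nm2_per_ns: 1.75, category: iii, charge: -1, n_H: 0, n_O: 2}
  - {name: HO2-,  D_nm2_per_ns: 1.4,  category: iii, charge: -1, n_H: 1, n_O: 2}

continuum:
  - {name: O2, charge: 0, n_H: 0, n_O: 2}

reactions:
  # radical-radical recombination and scavenging in pure water
  - {reactants: [OH, OH],       products: [H2O2],        k_per_M_per_s: 5.5e9}
  - {reactants: [OH, e_aq-],    products: [OH-],         k_per_M_per_s: 3.0e10}
  - {reactants: [OH, H],        products: [],            k_per_M_per_s: 2.0e10}
  - {reactants: [OH, H2],       products: [H],           k_per_M_per_s: 4.2e7}
  # NOTE: the slow OH + H2O2 -> HO2 channel (k ~ 3e7) is deliberately left
  # out so that, without dissolved O2, the oxygen-product category is
  # unreachable from primary/recombination species alone; at track
  # concentrations its contribution is negligible.
  - {reactants: [e_aq-, e_aq-], products: [H2, OH-, OH-], k_per_M_per_s: 5.5e9}
  - {reactants: [e_aq-, H],     products: [H2, OH-],     k_per_M_per_s: 2.5e10}
  - {reactants: [e_aq-, H3O+],  products: [H],           k_per_M_per_s: 2.3e10}
  - {reactants: [e_aq-, H2O2],  products: [OH, OH-],     k_per_M_per_s: 1.1e10}
  - {reactants: [H, H],         products: [H2],          k_per_M_per_s: 5.0e9}
  - {reactants: [H, H2O2],      products: [OH],          k_per_M_per_s: 9.0e7}
  - {reactants: [H, OH-],       products: [e_aq-],       k_per_M_per_s: 2.2e7}
  - {reactants: [H3O+, OH-],    products: [],            k_per_M_per_s: 1.43e11}
  # dissolved-oxygen channels (continuum reactant)
  - {reactants: [e_aq-, O2],    products: [O2-],         k_per_M_per_s: 1.9e10}
  - {reactants: [H, O2],        products: [HO2],         k_per_M_per_s: 2.1e10}
  # peroxyl / superoxide chemistry
  - {reactants: [OH, HO2],      products: [O2],          k_per_M_per_s: 6.0e9}
  - {reactants: [OH, O2-],      products: [O2, OH-],     k_per_M_per_s: 8.0e9}
  - {reactants: [e_aq-, HO2],   products: [HO2-],        k_per_M_per_s: 2.0e10}
  - {reactants: [e_aq-, O2-],   products: [HO2-, OH-],   k_per_M_per_s: 1.3e10}
  - {reactants: [H, HO2],       products: [H2O2],        k_per_M_per_s: 1.0e10}
  - {reactants: [H, O2-],       products: [HO2-],        k_per_M_per_s: 2.0e10}
  - {reactants: [H3O+, O2-],    products: [HO2],         k_per_M_per_s: 4.78e10}
  - {reactants: [H3O+, HO2-],   products: [H2O2],        k_per_M_per_s: 5.0e10}
  - {reactants: [HO2, HO2],     products: [H2O2, O2],    k_per_M_per_s: 4.2e5}
  - {reactants: [HO2, O2-],     products: [HO2-, O2],    k_per_M_per_s: 9.7e7}
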