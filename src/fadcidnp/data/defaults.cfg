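# Default biradical model parameters for the FAD flavin-adenine biradical.
# Values follow the published model-parameter table; the exchange amplitude
# J0 is the package's calibrated value (the printed amplitude is not
# compatible with any literal reading of the printed decay parameter; see
# docs/methods.md), with the decay parameter 0.214 read as a decay length
# in nm.
ga = 2.0034          # g factor of the adenine radical
gb = 2.0035          # g factor of the flavin radical
A = -0.7             # HFC of the observed nucleus (A8), mT
A_add = 1.67         # HFC of each additional spin-1/2 nucleus (flavin), mT
n_add = 4            # number of additional equivalent nuclei
J0 = -25.0           # exchange amplitude, mT (calibrated)
alpha = 0.214        # exchange decay length, nm
convention = decay_length_nm
r_contact = 0.49     # contact distance, nm (used by the contact-offset convention)
D = 2e-7             # effective radial diffusion coefficient, cm^2/s
G = 6.1e17           # mean-square fluctuating local field, s^-2
tau_u = 1e-12        # local-field correlation time, s
tau_rot = 8e-10      # rotational diffusion correlation time, s
kp = 2e10            # singlet recombination rate constant, s^-1
ks = 1e5             # scavenging rate, s^-1
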