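# Pairwise genetic distances and niche overlap between the six Milicia
# genetic clusters, transcribed from the published study this package
# re-analyses.  dmu2_ssr: Goldstein's (delta mu)^2 from SSR allele sizes;
# fst/ds: Weir-Cockerham theta and Nei's standard distance per marker set;
# niche_d: Schoener's D overlap of the modelled climate niches.
# The "global" row holds the published multi-group estimates (no global
# value was published for dmu2 or niche_d; cells left empty).
X,Y,dmu2_ssr,fst_ssr,ds_ssr,fst_snp,ds_snp,niche_d
K1,K2,2.726,0.185,0.486,0.759,0.632,0.180
K1,K3,3.030,0.250,0.491,0.569,0.608,0.292
K1,K4,4.328,0.270,0.531,0.677,0.655,0.303
K1,K5,3.892,0.343,1.122,0.782,0.398,0.479
K1,K6,10.795,0.301,1.030,0.568,0.091,0.046
K2,K3,2.231,0.237,0.370,0.220,0.130,0.129
K2,K4,2.876,0.245,0.356,0.286,0.150,0.078
K2,K5,7.193,0.440,1.081,0.756,1.043,0.060
K2,K6,14.100,0.455,1.647,0.700,0.624,0.114
K3,K4,0.351,0.052,0.049,0.051,0.024,0.475
K3,K5,4.758,0.381,0.641,0.522,0.543,0.280
K3,K6,8.026,0.409,0.924,0.533,0.570,0.200
K4,K5,6.587,0.411,0.619,0.616,0.599,0.237
K4,K6,9.800,0.431,0.882,0.622,0.631,0.068
K5,K6,8.624,0.577,1.324,0.740,0.340,0.070
global,,,0.333,0.771,0.560,0.469,
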