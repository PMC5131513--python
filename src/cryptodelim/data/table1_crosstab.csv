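# Cross-tabulation of hard cluster assignments (q > 0.5) for 435 Milicia
# individuals: SNP-based clusters in rows, SSR-based clusters in columns.
# Transcribed from the published study this package re-analyses.  The
# published rendering fixes the diagonal and the row/column margins; the
# off-diagonal cell placement shown here is the unique reconstruction
# consistent with those margins, and only the diagonal and margins are
# used numerically.
,K1,K2,K3,K4,K5,K6,UNDEFINED
K1,44,4,3,0,1,0,10
K2,1,30,4,0,0,0,2
K3,0,0,197,17,3,0,2
K4,0,0,5,67,0,0,0
K5,0,0,1,0,30,0,0
K6,0,0,0,0,0,12,1
UNDEFINED,0,0,0,0,0,0,1
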