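case,rheology,inlet,variable,value
2B,Cs,Parabolic,FA_pct,38.45
2B,CY,Parabolic,FA_pct,32.87
2B,HB,Parabolic,FA_pct,42.09
2B,N,Parabolic,FA_pct,39.87
2B,P,Parabolic,FA_pct,32.08
2B,Cs,Parabolic,FD_pct,5.11
2B,CY,Parabolic,FD_pct,5.22
2B,HB,Parabolic,FD_pct,4.79
2B,N,Parabolic,FD_pct,5.94
2B,P,Parabolic,FD_pct,6.28
2B,Cs,Plug,FA_pct,79.61
2B,CY,Plug,FA_pct,83.54
2B,HB,Plug,FA_pct,74.70
2B,N,Plug,FA_pct,78.37
2B,P,Plug,FA_pct,83.02
2B,Cs,Plug,FD_pct,7.05
2B,CY,Plug,FD_pct,5.99
2B,HB,Plug,FD_pct,8.90
2B,N,Plug,FD_pct,7.75
2B,P,Plug,FD_pct,6.03
2B,Cs,Womersley,FA_pct,46.05
2B,CY,Womersley,FA_pct,53.12
2B,HB,Womersley,FA_pct,50.48
2B,N,Womersley,FA_pct,30.63
2B,P,Womersley,FA_pct,60.54
2B,Cs,Womersley,FD_pct,16.78
2B,CY,Womersley,FD_pct,15.85
2B,HB,Womersley,FD_pct,15.43
2B,N,Womersley,FD_pct,10.29
2B,P,Womersley,FD_pct,13.34
7A,Cs,Parabolic,FA_pct,57.87
7A,CY,Parabolic,FA_pct,60.21
7A,HB,Parabolic,FA_pct,61.78
7A,N,Parabolic,FA_pct,57.14
7A,P,Parabolic,FA_pct,65.57
7A,Cs,Parabolic,FD_pct,5.87
7A,CY,Parabolic,FD_pct,6.31
7A,HB,Parabolic,FD_pct,6.06
7A,N,Parabolic,FD_pct,6.97
7A,P,Parabolic,FD_pct,6.94
7A,Cs,Plug,FA_pct,69.90
7A,CY,Plug,FA_pct,71.08
7A,HB,Plug,FA_pct,69.35
7A,N,Plug,FA_pct,68.82
7A,P,Plug,FA_pct,71.07
7A,Cs,Plug,FD_pct,17.96
7A,CY,Plug,FD_pct,16.94
7A,HB,Plug,FD_pct,19.00
7A,N,Plug,FD_pct,19.73
7A,P,Plug,FD_pct,16.48
7A,Cs,Womersley,FA_pct,73.84
7A,CY,Womersley,FA_pct,73.97
7A,HB,Womersley,FA_pct,74.44
7A,N,Womersley,FA_pct,74.70
7A,P,Womersley,FA_pct,73.72
7A,Cs,Womersley,FD_pct,12.91
7A,CY,Womersley,FD_pct,13.79
7A,HB,Womersley,FD_pct,12.95
7A,N,Womersley,FD_pct,10.87
7A,P,Womersley,FD_pct,12.79
14B,Cs,Parabolic,FA_pct,85.62
14B,CY,Parabolic,FA_pct,85.24
14B,HB,Parabolic,FA_pct,85.76
14B,N,Parabolic,FA_pct,86.72
14B,P,Parabolic,FA_pct,84.88
14B,Cs,Parabolic,FD_pct,5.79
14B,CY,Parabolic,FD_pct,6.03
14B,HB,Parabolic,FD_pct,5.87
14B,N,Parabolic,FD_pct,5.42
14B,P,Parabolic,FD_pct,6.10
14B,Cs,Plug,FA_pct,83.75
14B,CY,Plug,FA_pct,83.85
14B,HB,Plug,FA_pct,83.28
14B,N,Plug,FA_pct,85.32
14B,P,Plug,FA_pct,83.36
14B,Cs,Plug,FD_pct,6.53
14B,CY,Plug,FD_pct,6.60
14B,HB,Plug,FD_pct,7.19
14B,N,Plug,FD_pct,6.21
14B,P,Plug,FD_pct,6.89
14B,Cs,Womersley,FA_pct,82.90
14B,CY,Womersley,FA_pct,83.14
14B,HB,Womersley,FA_pct,82.60
14B,N,Womersley,FA_pct,82.39
14B,P,Womersley,FA_pct,82.65
14B,Cs,Womersley,FD_pct,6.75
14B,CY,Womersley,FD_pct,6.83
14B,HB,Womersley,FD_pct,7.31
14B,N,Womersley,FD_pct,6.97
14B,P,Womersley,FD_pct,6.99
16A,Cs,Parabolic,FA_pct,88.11
16A,CY,Parabolic,FA_pct,87.08
16A,HB,Parabolic,FA_pct,88.77
16A,N,Parabolic,FA_pct,90.74
16A,P,Parabolic,FA_pct,84.92
16A,Cs,Parabolic,FD_pct,6.63
16A,CY,Parabolic,FD_pct,6.97
16A,HB,Parabolic,FD_pct,6.29
16A,N,Parabolic,FD_pct,5.64
16A,P,Parabolic,FD_pct,7.61
16A,Cs,Plug,FA_pct,79.80
16A,CY,Plug,FA_pct,79.12
16A,HB,Plug,FA_pct,80.12
16A,N,Plug,FA_pct,80.64
16A,P,Plug,FA_pct,78.19
16A,Cs,Plug,FD_pct,11.24
16A,CY,Plug,FD_pct,12.07
16A,HB,Plug,FD_pct,11.24
16A,N,Plug,FD_pct,8.50
16A,P,Plug,FD_pct,12.20
16A,Cs,Womersley,FA_pct,80.87
16A,CY,Womersley,FA_pct,81.48
16A,HB,Womersley,FA_pct,80.37
16A,N,Womersley,FA_pct,81.59
16A,P,Womersley,FA_pct,80.46
16A,Cs,Womersley,FD_pct,10.82
16A,CY,Womersley,FD_pct,9.90
16A,HB,Womersley,FD_pct,9.84
16A,N,Womersley,FD_pct,9.53
16A,P,Womersley,FD_pct,10.89
31A,Cs,Parabolic,FA_pct,34.44
31A,CY,Parabolic,FA_pct,35.62
31A,HB,Parabolic,FA_pct,34.59
31A,N,Parabolic,FA_pct,35.67
31A,P,Parabolic,FA_pct,37.35
31A,Cs,Parabolic,FD_pct,18.06
31A,CY,Parabolic,FD_pct,19.03
31A,HB,Parabolic,FD_pct,17.31
31A,N,Parabolic,FD_pct,15.91
31A,P,Parabolic,FD_pct,19.13
31A,Cs,Plug,FA_pct,35.06
31A,CY,Plug,FA_pct,36.10
31A,HB,Plug,FA_pct,36.25
31A,N,Plug,FA_pct,34.27
31A,P,Plug,FA_pct,36.81
31A,Cs,Plug,FD_pct,42.48
31A,CY,Plug,FD_pct,42.30
31A,HB,Plug,FD_pct,39.95
31A,N,Plug,FD_pct,40.81
31A,P,Plug,FD_pct,40.41
31A,Cs,Womersley,FA_pct,35.38
31A,CY,Womersley,FA_pct,37.43
31A,HB,Womersley,FA_pct,40.41
31A,N,Womersley,FA_pct,39.89
31A,P,Womersley,FA_pct,37.44
31A,Cs,Womersley,FD_pct,38.37
31A,CY,Womersley,FD_pct,39.65
31A,HB,Womersley,FD_pct,35.53
31A,N,Womersley,FD_pct,32.68
31A,P,Womersley,FD_pct,36.35
41B,Cs,Parabolic,FA_pct,28.96
41B,CY,Parabolic,FA_pct,30.63
41B,HB,Parabolic,FA_pct,30.40
41B,N,Parabolic,FA_pct,54.89
41B,P,Parabolic,FA_pct,39.39
41B,Cs,Parabolic,FD_pct,17.29
41B,CY,Parabolic,FD_pct,17.83
41B,HB,Parabolic,FD_pct,14.86
41B,N,Parabolic,FD_pct,7.44
41B,P,Parabolic,FD_pct,17.85
41B,Cs,Plug,FA_pct,30.10
41B,CY,Plug,FA_pct,24.99
41B,HB,Plug,FA_pct,29.96
41B,N,Plug,FA_pct,27.29
41B,P,Plug,FA_pct,16.99
41B,Cs,Plug,FD_pct,22.64
41B,CY,Plug,FD_pct,23.49
41B,HB,Plug,FD_pct,26.74
41B,N,Plug,FD_pct,9.87
41B,P,Plug,FD_pct,36.70
41B,Cs,Womersley,FA_pct,29.15
41B,CY,Womersley,FA_pct,22.94
41B,HB,Womersley,FA_pct,19.83
41B,N,Womersley,FA_pct,20.77
41B,P,Womersley,FA_pct,22.09
41B,Cs,Womersley,FD_pct,32.74
41B,CY,Womersley,FD_pct,35.03
41B,HB,Womersley,FD_pct,38.73
41B,N,Womersley,FD_pct,14.63
41B,P,Womersley,FD_pct,43.93
63A,Cs,Parabolic,FA_pct,23.69
63A,CY,Parabolic,FA_pct,23.50
63A,HB,Parabolic,FA_pct,22.99
63A,N,Parabolic,FA_pct,10.07
63A,P,Parabolic,FA_pct,25.16
63A,Cs,Parabolic,FD_pct,9.07
63A,CY,Parabolic,FD_pct,13.15
63A,HB,Parabolic,FD_pct,8.56
63A,N,Parabolic,FD_pct,8.96
63A,P,Parabolic,FD_pct,15.48
63A,Cs,Plug,FA_pct,7.69
63A,CY,Plug,FA_pct,9.67
63A,HB,Plug,FA_pct,6.59
63A,N,Plug,FA_pct,4.91
63A,P,Plug,FA_pct,4.87
63A,Cs,Plug,FD_pct,21.77
63A,CY,Plug,FD_pct,22.26
63A,HB,Plug,FD_pct,21.56
63A,N,Plug,FD_pct,13.53
63A,P,Plug,FD_pct,19.72
63A,Cs,Womersley,FA_pct,7.61
63A,CY,Womersley,FA_pct,8.75
63A,HB,Womersley,FA_pct,8.15
63A,N,Womersley,FA_pct,7.26
63A,P,Womersley,FA_pct,13.94
63A,Cs,Womersley,FD_pct,20.78
63A,CY,Womersley,FD_pct,19.83
63A,HB,Womersley,FD_pct,22.89
63A,N,Womersley,FD_pct,22.97
63A,P,Womersley,FD_pct,18.90
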