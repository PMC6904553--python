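subject,mark,fle_mm
A,a,63.3
A,b,56.5
A,c,11.4
A,d,18.2
A,e,8.6
A,f,13.0
A,g,18.3
A,h,54.6
A,i,21.3
A,j,16.7
A,k,16.3
A,l,38.6
A,m,34.9
A,n,31.6
A,o,37.6
B,a,6.3
B,b,9.6
B,c,41.8
B,d,42.9
B,e,25.1
B,f,12.2
B,g,34.2
B,h,46.2
B,i,21.8
B,j,30.7
B,k,6.1
B,l,38.9
B,m,30.3
B,n,38.4
B,o,89.5
C,a,12.5
C,b,36.3
C,c,13.6
C,d,24.1
C,e,28.1
C,f,8.7
C,g,29.9
C,h,19.8
C,i,58.0
C,j,31.4
C,k,9.0
C,l,35.3
C,m,57.5
C,n,28.7
C,o,34.4
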