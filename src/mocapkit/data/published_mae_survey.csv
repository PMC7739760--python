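joint,axis,task,condition,mae_mm
shoulder,X,walk,1K,28.4
shoulder,X,walk,4K,24.6
shoulder,X,jump,1K,27.1
shoulder,X,jump,4K,20.9
shoulder,X,throw,1K,21.7
shoulder,X,throw,4K,19.3
shoulder,Y,walk,1K,17.0
shoulder,Y,walk,4K,49.7
shoulder,Y,jump,1K,12.5
shoulder,Y,jump,4K,11.9
shoulder,Y,throw,1K,27.7
shoulder,Y,throw,4K,32.5
shoulder,Z,walk,1K,17.9
shoulder,Z,walk,4K,16.5
shoulder,Z,jump,1K,29.5
shoulder,Z,jump,4K,30.8
shoulder,Z,throw,1K,15.8
shoulder,Z,throw,4K,13.9
elbow,X,walk,1K,4.32
elbow,X,walk,4K,6.96
elbow,X,jump,1K,9.36
elbow,X,jump,4K,8.25
elbow,X,throw,1K,47.3
elbow,X,throw,4K,45.2
elbow,Y,walk,1K,37.0
elbow,Y,walk,4K,66.8
elbow,Y,jump,1K,27.0
elbow,Y,jump,4K,20.5
elbow,Y,throw,1K,28.7
elbow,Y,throw,4K,35.1
elbow,Z,walk,1K,21.7
elbow,Z,walk,4K,22.2
elbow,Z,jump,1K,26.9
elbow,Z,jump,4K,35.3
elbow,Z,throw,1K,38.0
elbow,Z,throw,4K,38.9
wrist,X,walk,1K,5.78
wrist,X,walk,4K,7.52
wrist,X,jump,1K,8.96
wrist,X,jump,4K,8.31
wrist,X,throw,1K,40.6
wrist,X,throw,4K,47.5
wrist,Y,walk,1K,19.0
wrist,Y,walk,4K,44.2
wrist,Y,jump,1K,13.2
wrist,Y,jump,4K,20.6
wrist,Y,throw,1K,28.7
wrist,Y,throw,4K,40.3
wrist,Z,walk,1K,15.7
wrist,Z,walk,4K,16.8
wrist,Z,jump,1K,23.8
wrist,Z,jump,4K,38.9
wrist,Z,throw,1K,24.7
wrist,Z,throw,4K,26.7
hip,X,walk,1K,9.65
hip,X,walk,4K,7.67
hip,X,jump,1K,8.77
hip,X,jump,4K,6.01
hip,X,throw,1K,29.5
hip,X,throw,4K,25.0
hip,Y,walk,1K,21.3
hip,Y,walk,4K,49.4
hip,Y,jump,1K,15.0
hip,Y,jump,4K,14.2
hip,Y,throw,1K,13.5
hip,Y,throw,4K,20.8
hip,Z,walk,1K,24.4
hip,Z,walk,4K,20.6
hip,Z,jump,1K,31.0
hip,Z,jump,4K,32.1
hip,Z,throw,1K,27.2
hip,Z,throw,4K,23.5
knee,X,walk,1K,6.41
knee,X,walk,4K,4.09
knee,X,jump,1K,7.74
knee,X,jump,4K,6.47
knee,X,throw,1K,15.2
knee,X,throw,4K,13.1
knee,Y,walk,1K,25.9
knee,Y,walk,4K,48.2
knee,Y,jump,1K,8.48
knee,Y,jump,4K,18.3
knee,Y,throw,1K,13.8
knee,Y,throw,4K,19.1
knee,Z,walk,1K,10.1
knee,Z,walk,4K,11.4
knee,Z,jump,1K,14.8
knee,Z,jump,4K,20.9
knee,Z,throw,1K,24.4
knee,Z,throw,4K,20.4
ankle,X,walk,1K,9.68
ankle,X,walk,4K,8.73
ankle,X,jump,1K,9.82
ankle,X,jump,4K,6.67
ankle,X,throw,1K,12.3
ankle,X,throw,4K,19.1
ankle,Y,walk,1K,28.6
ankle,Y,walk,4K,58.1
ankle,Y,jump,1K,9.31
ankle,Y,jump,4K,11.0
ankle,Y,throw,1K,17.7
ankle,Y,throw,4K,22.2
ankle,Z,walk,1K,11.7
ankle,Z,walk,4K,20.7
ankle,Z,jump,1K,20.6
ankle,Z,jump,4K,27.9
ankle,Z,throw,1K,12.4
ankle,Z,throw,4K,20.3
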